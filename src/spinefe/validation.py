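"""Full-field comparison of predicted and measured surface displacements.

The comparison follows the standard full-field (DIC-style) validation
recipe for bone FE models: measured displacement vectors are averaged
over a sphere of radius R (the registration RMSE) centred on each model
surface node in the region of interest, influential points are removed
with a Cook's-distance rule, and each displacement component is
regressed predicted-vs-measured.  The summary metrics per region and
component are R^2, slope, intercept, RMSE, %RMSE (RMSE normalized by the
largest measured component magnitude in the region), the mean percentage
error and the maximum absolute error, together with pointwise error
fields and Bland-Altman agreement pairs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial import cKDTree
from scipy.stats import linregress

from .fe import FESolution
from .registration import SurfaceField

__all__ = [
    "ValidationConfig",
    "PairedSamples",
    "ComponentMetrics",
    "ValidationReport",
    "pair_and_average",
    "cooks_filter",
    "regress_component",
    "diff_field",
    "bland_altman",
    "validate_roi",
]

#: component label -> coordinate axis (right-left, antero-posterior,
#: superior-inferior in the default model frame)
DEFAULT_AXES = {"RL": 0, "AP": 1, "SI": 2}


@dataclass(frozen=True)
class ValidationConfig:
    radius: float = 0.53                 # mm; averaging sphere = registration RMSE
    cook_multiplier: float = 4.0
    components: tuple = ("RL", "AP", "SI")
    axes: dict = field(default_factory=lambda: dict(DEFAULT_AXES))
    min_points_per_sphere: int = 1
    small_disp_guard: float = 1e-3       # mm; |U_DIC| below this excluded from AvgErr%

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("averaging radius must be positive")
        if self.cook_multiplier <= 0:
            raise ValueError("cook_multiplier must be positive")


@dataclass
class PairedSamples:
    """Per-node pairing of predicted and sphere-averaged measured vectors."""

    node_ids: np.ndarray
    positions: np.ndarray      # (n, 3) node coordinates, mm
    u_fem: np.ndarray          # (n, 3) mm
    u_dic: np.ndarray          # (n, 3) mm
    n_dropped: int             # RoI nodes without enough cloud points

    def __len__(self) -> int:
        return self.node_ids.shape[0]


@dataclass
class ComponentMetrics:
    component: str
    r2: float
    slope: float
    intercept: float
    rmse: float                # mm
    pct_rmse: float            # %
    avg_err_pct: float         # %
    max_err: float             # mm
    n_points: int
    n_outliers_removed: int
    n_guarded: int             # excluded from AvgErr% by the small-displacement guard


def pair_and_average(roi_nodes: np.ndarray, solution: FESolution,
                     fld: SurfaceField, cfg: ValidationConfig) -> PairedSamples:
    """Average the measured cloud over a sphere of radius R at each RoI node.

    U_DIC at a node is the unweighted mean of all cloud displacement
    vectors within ``cfg.radius`` of the node; nodes with fewer than
    ``cfg.min_points_per_sphere`` neighbours are dropped (and counted).
    The field must already be registered into the model frame.
    """
    roi_nodes = np.asarray(roi_nodes, dtype=np.int64)
    pos = solution.mesh.nodes[roi_nodes]
    tree = cKDTree(fld.points)
    hoods = tree.query_ball_point(pos, cfg.radius)
    keep, u_dic = [], []
    for i, hood in enumerate(hoods):
        if len(hood) >= cfg.min_points_per_sphere and len(hood) > 0:
            keep.append(i)
            u_dic.append(fld.displacements[hood].mean(axis=0))
    if not keep:
        raise ValueError(
            f"no RoI node has cloud points within R={cfg.radius} mm; "
            "increase the averaging radius"
        )
    keep = np.array(keep)
    return PairedSamples(
        node_ids=roi_nodes[keep],
        positions=pos[keep],
        u_fem=solution.u[roi_nodes[keep]],
        u_dic=np.array(u_dic),
        n_dropped=len(roi_nodes) - len(keep),
    )


def cooks_filter(x: np.ndarray, y: np.ndarray, multiplier: float = 4.0) -> np.ndarray:
    """Inlier mask from Cook's distance on the simple regression y ~ x.

    Points with D_i greater than ``multiplier`` times the mean D are
    flagged as outliers, in a single pass.  With fewer than 4 points the
    filter is skipped (all-true mask) with a warning.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.shape[0]
    if n < 4:
        warnings.warn("fewer than 4 points; Cook's filtering skipped", stacklevel=2)
        return np.ones(n, dtype=bool)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    scale = max(1.0, float(np.abs(y).max()))
    if np.abs(model.resid).max() <= 1e-12 * scale:
        # numerically perfect fit: Cook's distances are rounding noise
        return np.ones(n, dtype=bool)
    d = model.get_influence().cooks_distance[0]
    mean_d = d.mean()
    if mean_d == 0:
        return np.ones(n, dtype=bool)
    return d <= multiplier * mean_d


def regress_component(pairs: PairedSamples, component: str,
                      cfg: ValidationConfig = ValidationConfig()) -> ComponentMetrics:
    """Per-component agreement metrics after Cook's-distance filtering.

    Ordinary least squares of the predicted component against the
    measured one; RMSE of (measured - predicted) over the inliers; %RMSE
    normalized by the largest measured component magnitude in the region;
    mean percentage error with a small-displacement guard; maximum
    absolute error.
    """
    ax = cfg.axes[component]
    x = pairs.u_dic[:, ax]
    y = pairs.u_fem[:, ax]
    if len(pairs) < 3:
        raise ValueError("at least 3 paired samples are required for regression")
    if np.ptp(x) == 0:
        raise ValueError(f"measured {component} component has zero variance")
    mask = cooks_filter(x, y, cfg.cook_multiplier)
    xi, yi = x[mask], y[mask]
    fit = linregress(xi, yi)
    err = np.abs(xi - yi)
    rmse = float(np.sqrt(np.mean((xi - yi) ** 2)))
    norm = float(np.max(np.abs(xi)))
    guard = np.abs(xi) >= cfg.small_disp_guard
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * err[guard] / np.abs(xi[guard])
    return ComponentMetrics(
        component=component,
        r2=float(fit.rvalue ** 2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        rmse=rmse,
        pct_rmse=100.0 * rmse / norm if norm > 0 else np.nan,
        avg_err_pct=float(pct.mean()) if pct.size else np.nan,
        max_err=float(err.max()),
        n_points=int(mask.sum()),
        n_outliers_removed=int((~mask).sum()),
        n_guarded=int((~guard).sum()),
    )


def diff_field(pairs: PairedSamples) -> np.ndarray:
    """Per-node resultant error: Euclidean norm of the component errors."""
    return np.linalg.norm(pairs.u_dic - pairs.u_fem, axis=1)


@dataclass
class BlandAltman:
    means: np.ndarray
    differences: np.ndarray
    bias: float
    loa_low: float
    loa_high: float


def bland_altman(pairs: PairedSamples, component: str | None = None,
                 cfg: ValidationConfig = ValidationConfig()) -> BlandAltman:
    """Agreement pairs: per-point mean vs difference.

    With a component label, the difference is the signed measured-minus-
    predicted component; with ``component=None`` the difference is the
    resultant error magnitude (Diff) against the mean of the measured and
    predicted displacement magnitudes.
    """
    if len(pairs) < 2:
        raise ValueError("at least 2 pairs are required")
    if component is None:
        means = 0.5 * (np.linalg.norm(pairs.u_dic, axis=1)
                       + np.linalg.norm(pairs.u_fem, axis=1))
        diffs = diff_field(pairs)
    else:
        ax = cfg.axes[component]
        means = 0.5 * (pairs.u_dic[:, ax] + pairs.u_fem[:, ax])
        diffs = pairs.u_dic[:, ax] - pairs.u_fem[:, ax]
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1)) if len(pairs) > 1 else 0.0
    return BlandAltman(means, diffs, bias, bias - 1.96 * sd, bias + 1.96 * sd)


@dataclass
class ValidationReport:
    """Per-RoI, per-component metrics plus pointwise error fields."""

    metrics: dict                       # roi -> {component -> ComponentMetrics}
    pairs: dict                         # roi -> PairedSamples
    pointwise: dict                     # roi -> DataFrame (Error/Error%/Diff per node)
    config: ValidationConfig

    def to_frame(self) -> pd.DataFrame:
        """Metric table shaped rows=metrics, columns=(RoI, component)."""
        cols = {}
        for roi, comps in self.metrics.items():
            for comp, m in comps.items():
                cols[(roi, comp)] = {
                    "R2": m.r2, "Slope": m.slope, "Intercept": m.intercept,
                    "RMSE (mm)": m.rmse, "RMSE %": m.pct_rmse,
                    "Average Error %": m.avg_err_pct, "Maximum Error (mm)": m.max_err,
                    "n points": m.n_points, "n outliers removed": m.n_outliers_removed,
                }
        return pd.DataFrame(cols)

    def to_json(self) -> str:
        out = {
            roi: {comp: vars(m) for comp, m in comps.items()}
            for roi, comps in self.metrics.items()
        }
        return json.dumps(out, indent=2)


def validate_roi(solution: FESolution, fields: dict, roi_nodes: dict,
                 cfg: ValidationConfig = ValidationConfig()) -> ValidationReport:
    """Run the full comparison for every region of interest.

    ``fields`` maps RoI label -> registered SurfaceField, ``roi_nodes``
    maps the same labels -> surface node ids of the model.
    """
    metrics: dict = {}
    all_pairs: dict = {}
    pointwise: dict = {}
    for roi, fld in fields.items():
        pairs = pair_and_average(roi_nodes[roi], solution, fld, cfg)
        comps = {c: regress_component(pairs, c, cfg) for c in cfg.components}
        err = np.abs(pairs.u_dic - pairs.u_fem)
        with np.errstate(divide="ignore", invalid="ignore"):
            err_pct = np.where(np.abs(pairs.u_dic) >= cfg.small_disp_guard,
                               100.0 * err / np.abs(pairs.u_dic), np.nan)
        pointwise[roi] = pd.DataFrame(
            {
                "node": pairs.node_ids,
                "x": pairs.positions[:, 0],
                "y": pairs.positions[:, 1],
                "z": pairs.positions[:, 2],
                **{f"Error_{c}": err[:, cfg.axes[c]] for c in cfg.components},
                **{f"ErrorPct_{c}": err_pct[:, cfg.axes[c]] for c in cfg.components},
                "Diff": diff_field(pairs),
            }
        )
        metrics[roi] = comps
        all_pairs[roi] = pairs
    return ValidationReport(metrics, all_pairs, pointwise, cfg)
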