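"""Reactivity normalization.

Two routes, matching the two families of stop-based normalization:

* :func:`window_reactivity` — sliding-window Winsorized normalization.
  Random priming is strongly biased, so absolute counts are not
  comparable along the molecule; within a 70-nt window, counts above the
  window's 95th percentile are capped at it (upper-tail Winsorization)
  and everything is divided by that percentile, giving in-window
  reactivities in [0, 1]. A position's final reactivity is the average
  of its in-window values across every window containing it.
* :func:`delta_tcr` — no-reagent-control background subtraction on
  termination-coverage ratios,
  dTCR = (TCR_sample − α·TCR_control) / (1 − α·TCR_control),
  with the background scaling α chosen by grid search maximizing the AUC
  against a reference structure (:func:`optimize_alpha`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .counting import TcrProfile
from .errors import ConfigurationError, DataError
from .structeval import EvalConfig, StructureAnnotation, evaluate_auc

logger = logging.getLogger(__name__)


@dataclass
class ReactivityProfile:
    """Per-position reactivities; NaN marks missing positions.

    ``method`` is ``window`` (values in [0,1]) or ``delta_tcr`` (values may
    be negative unless clamped; the clamp setting is recorded in params).
    """

    rna_id: str
    values: np.ndarray
    method: str
    params: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.values)


@dataclass
class WindowConfig:
    """Sliding-window normalization parameters.

    window: window length in nt (default 70 — wide enough for a stable
    95th-percentile estimate, narrow enough to track priming bias; sizes
    from ~30 to several hundred behave similarly).
    percentile: the Winsorization/normalization percentile (default 95).
    """

    window: int = 70
    percentile: float = 95.0

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ConfigurationError(f"window must be >= 2, got {self.window}")
        if not (0 < self.percentile < 100):
            raise ConfigurationError(
                f"percentile must be in (0, 100), got {self.percentile}"
            )


@dataclass
class AlphaSearchConfig:
    """Grid for the background-scaling search; 1.0 is excluded by default to
    keep the dTCR denominator away from zero."""

    alpha_grid: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.0, 1.0, 0.01), 10)
    )
    eval_config: EvalConfig = field(default_factory=EvalConfig)

    def __post_init__(self) -> None:
        grid = np.asarray(self.alpha_grid, dtype=float)
        if grid.size == 0:
            raise ConfigurationError("alpha grid is empty")
        if (np.diff(grid) <= 0).any() or grid[0] < 0:
            raise ConfigurationError("alpha grid must be increasing and nonnegative")
        self.alpha_grid = grid


def window_reactivity(
    counts: np.ndarray,
    config: WindowConfig | None = None,
    rna_id: str = "rna",
) -> ReactivityProfile:
    """Sliding-window Winsorized normalization of a count vector.

    Every contiguous window of length min(window, L) is visited once; in
    each, q = the configured percentile of the window's counts (linear
    interpolation between order statistics), the in-window reactivity is
    min(count, q)/q, and windows with q = 0 contribute nothing ("no signal
    observed" is not "zero reactivity"). The profile value at a position is
    the mean of its in-window reactivities; NaN when every window was empty.
    """
    config = config or WindowConfig()
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or len(counts) == 0:
        raise DataError("counts must be a non-empty 1-D vector")
    if np.isnan(counts).any() or (counts < 0).any():
        raise DataError("counts must be nonnegative and non-missing")
    L = len(counts)
    w = min(config.window, L)
    sums = np.zeros(L)
    n_windows = np.zeros(L, dtype=np.int64)
    for s in range(L - w + 1):
        seg = counts[s : s + w]
        q = float(np.percentile(seg, config.percentile))
        if q <= 0:
            continue
        sums[s : s + w] += np.minimum(seg, q) / q
        n_windows[s : s + w] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(n_windows > 0, sums / n_windows, np.nan)
    return ReactivityProfile(
        rna_id,
        values,
        method="window",
        params={"window": config.window, "percentile": config.percentile},
    )


def delta_tcr(
    tcr_sample: TcrProfile,
    tcr_control: TcrProfile,
    alpha: float,
    clamp: bool = False,
) -> ReactivityProfile:
    """Background-corrected reactivity (TCR_S − α·TCR_C) / (1 − α·TCR_C).

    Missing wherever either input is missing; positions where α·TCR_C >= 1
    (denominator non-positive) are set missing with a warning. Values are
    not clipped to [0, 1] unless ``clamp`` is set.
    """
    if alpha < 0:
        raise ConfigurationError(f"alpha must be >= 0, got {alpha}")
    if tcr_sample.length != tcr_control.length:
        raise DataError(
            f"TCR length mismatch: {tcr_sample.length} vs {tcr_control.length}"
        )
    ts = tcr_sample.tcr
    tc = tcr_control.tcr
    denom = 1.0 - alpha * tc
    with np.errstate(invalid="ignore", divide="ignore"):
        values = (ts - alpha * tc) / denom
    degenerate = ~np.isnan(denom) & (denom <= 0)
    if degenerate.any():
        logger.warning(
            "delta_tcr: %d positions with alpha*TCR_control >= 1 set to missing",
            int(degenerate.sum()),
        )
        values = np.where(degenerate, np.nan, values)
    if clamp:
        values = np.clip(values, 0.0, 1.0)
    return ReactivityProfile(
        tcr_sample.rna_id,
        values,
        method="delta_tcr",
        params={"alpha": float(alpha), "clamp": bool(clamp)},
    )


def optimize_alpha(
    tcr_sample: TcrProfile,
    tcr_control: TcrProfile,
    annotation: StructureAnnotation,
    config: AlphaSearchConfig | None = None,
) -> tuple[float, ReactivityProfile, float]:
    """Grid-search α maximizing the structure signal (AUC) of dTCR.

    Rather than estimating the control's contribution to the probed sample,
    every α on the grid is evaluated and the AUC maximizer returned; ties
    break toward the smallest α (least background assumed).
    """
    config = config or AlphaSearchConfig()
    best_alpha = None
    best_auc = -np.inf
    best_profile = None
    for alpha in config.alpha_grid:
        profile = delta_tcr(tcr_sample, tcr_control, float(alpha))
        auc = evaluate_auc(profile.values, annotation, config.eval_config).auc
        if auc > best_auc:
            best_alpha, best_auc, best_profile = float(alpha), auc, profile
    assert best_profile is not None
    return best_alpha, best_profile, best_auc


def write_reactivity_tsv(path, profile: ReactivityProfile) -> None:
    """TSV: rna_id, position, reactivity, method, and the parameters used."""
    keys = sorted(profile.params)
    with open(path, "w") as fh:
        fh.write("rna_id\tposition\treactivity\tmethod\t" + "\t".join(keys) + "\n")
        extra = "\t".join(str(profile.params[k]) for k in keys)
        for i, v in enumerate(profile.values, 1):
            val = "" if np.isnan(v) else f"{v:.6g}"
            fh.write(f"{profile.rna_id}\t{i}\t{val}\t{profile.method}\t{extra}\n")
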