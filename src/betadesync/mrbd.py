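"""Grand-average significance mask and masked MRBD extraction.

The mask is built from the grand-average dB matrix (mean over every
participant x electrode x condition matrix, blind to group labels).  For
each candidate cell in the beta band (13-30 Hz) and a stage window, the
cell's value is tested against the distribution of grand-average values
across the rest-stage time points at the same frequency: a two-sided
single-observation t-test (prediction-interval form), which is exactly
t-distributed when stage and rest cells share one distribution, so the
Bonferroni threshold controls false inclusions at the intended level.
Cells with
p < alpha / (n_frequencies x n_timepoints of the full decomposition grid)
enter the mask — a Bonferroni correction over the whole matrix, not just
the candidate cells.

The average dB value over the masked cells of a stage is then extracted
per participant x electrode x condition: the MRBD value used by the
statistics layer (negative = desynchronization).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .simulate import electrode_hemisphere, electrode_region
from .task import TrialTimeline
from .tfr import TFRMatrix, window_columns

__all__ = [
    "BETA_BAND",
    "DegenerateTestError",
    "SignificanceMask",
    "grand_average",
    "build_mask",
    "extract_mrbd",
]

BETA_BAND = (13.0, 30.0)

MRBD_COLUMNS = [
    "participant",
    "group",
    "electrode",
    "region",
    "hemisphere",
    "condition",
    "stage",
    "mrbd_db",
]


class DegenerateTestError(ValueError):
    """Raised when a rest-stage sample has zero variance."""


@dataclass
class SignificanceMask:
    """Boolean inclusion mask on beta rows x one stage window's columns."""

    include: np.ndarray  # (n_beta_freqs, n_stage_cols) bool
    pvalues: np.ndarray  # same shape
    freq_indices: np.ndarray  # rows of the full grid (beta band)
    col_indices: np.ndarray  # columns of the full grid (stage window)
    freqs: np.ndarray
    times: np.ndarray
    stage: str
    alpha: float
    cell_threshold: float
    meta: dict = field(default_factory=dict)

    @property
    def included_fraction(self) -> float:
        """Percent of candidate beta cells included in the mask."""
        return 100.0 * float(self.include.mean())

    @property
    def n_included(self) -> int:
        return int(self.include.sum())


def grand_average(tfrs: list[TFRMatrix]) -> TFRMatrix:
    """Cellwise mean across all participant x electrode x condition matrices."""
    if not tfrs:
        raise ValueError("need at least one TFR")
    first = tfrs[0]
    for t in tfrs[1:]:
        if not first.same_grid(t):
            raise ValueError("TFR grids do not match")
    mean = np.mean([t.power for t in tfrs], axis=0)
    valid = None
    if any(t.valid is not None for t in tfrs):
        valid = np.logical_and.reduce([t.valid_or_all() for t in tfrs])
    return TFRMatrix(
        mean,
        first.freqs.copy(),
        first.times.copy(),
        first.scale,
        baseline_window=first.baseline_window,
        valid=valid,
        meta={"n_matrices": len(tfrs)},
    )


def build_mask(
    grand: TFRMatrix,
    stage: str,
    timeline: TrialTimeline | None = None,
    alpha: float = 0.05,
    beta_band: tuple[float, float] = BETA_BAND,
    negative_only: bool = False,
) -> SignificanceMask:
    """Bonferroni-thresholded significance mask for one stage.

    ``negative_only`` restricts inclusion to desynchronized cells (value
    below the rest mean); off by default — inclusion is purely by p-value.
    """
    timeline = timeline or TrialTimeline()
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if stage not in ("planning", "execution"):
        raise ValueError("stage must be 'planning' or 'execution'")
    window = timeline.plan_window if stage == "planning" else timeline.exec_window
    cols = window_columns(grand.times, window)
    rest_cols = window_columns(grand.times, timeline.rest_window)
    if len(cols) == 0 or len(rest_cols) < 3:
        raise ValueError("stage or rest window not resolvable on the TFR grid")
    rows = np.nonzero(
        (grand.freqs >= beta_band[0]) & (grand.freqs <= beta_band[1])
    )[0]
    if len(rows) == 0:
        raise ValueError("no frequencies inside the beta band")

    n_cells_total = grand.power.shape[0] * grand.power.shape[1]
    threshold = alpha / n_cells_total

    # the rest sample per frequency uses edge-valid columns only: the rest
    # window abuts the epoch boundary and the first wavelet half-length of
    # columns is contaminated by the padding
    validity = grand.valid_or_all()
    rest_mean = np.empty(len(rows))
    rest_sd = np.empty(len(rows))
    rest_n = np.empty(len(rows), dtype=int)
    for i, r in enumerate(rows):
        usable = rest_cols[validity[r, rest_cols]]
        if len(usable) < 3:
            raise ValueError(
                f"fewer than 3 edge-valid rest time points at "
                f"{grand.freqs[r]:g} Hz"
            )
        sample = grand.power[r, usable]
        rest_mean[i] = sample.mean()
        rest_sd[i] = sample.std(ddof=1)
        rest_n[i] = len(usable)
    degenerate = rest_sd == 0
    if np.any(degenerate):
        raise DegenerateTestError(
            "zero variance in the rest-stage sample at frequencies "
            f"{grand.freqs[rows[degenerate]]}"
        )
    cells = grand.power[np.ix_(rows, cols)]  # (n_beta, n_stage)
    # single-observation t: the candidate cell is scored against the rest
    # distribution (prediction-interval form, exactly t-distributed under
    # an iid null), not against the rest mean's standard error
    t = (rest_mean[:, None] - cells) / (
        rest_sd[:, None] * np.sqrt(1.0 + 1.0 / rest_n)[:, None]
    )
    pvalues = 2.0 * sp_stats.t.sf(np.abs(t), df=rest_n[:, None] - 1)
    include = (pvalues < threshold) & validity[np.ix_(rows, cols)]
    if negative_only:
        include &= cells < rest_mean[:, None]
    return SignificanceMask(
        include=include,
        pvalues=pvalues,
        freq_indices=rows,
        col_indices=cols,
        freqs=grand.freqs[rows],
        times=grand.times[cols],
        stage=stage,
        alpha=alpha,
        cell_threshold=threshold,
        meta={"n_cells_total": n_cells_total, "negative_only": negative_only},
    )


def extract_mrbd(
    tfrs: list[TFRMatrix],
    masks: dict[str, SignificanceMask] | SignificanceMask,
) -> pd.DataFrame:
    """Mean masked dB per participant x electrode x condition x stage.

    ``tfrs`` are the dB-normalized per-participant/electrode/condition
    matrices, with 'participant', 'group', 'electrode' and 'condition' in
    their ``meta``.  Region and hemisphere are derived from the electrode
    label (F/C/P -> frontal/central/parietal; odd index -> left).
    """
    if isinstance(masks, SignificanceMask):
        masks = {masks.stage: masks}
    if not tfrs:
        raise ValueError("need at least one TFR")
    for stage, mask in masks.items():
        if mask.n_included == 0:
            raise ValueError(f"empty mask for stage {stage!r}")
    rows = []
    for tfr in tfrs:
        meta = tfr.meta
        for key in ("participant", "group", "electrode", "condition"):
            if key not in meta:
                raise ValueError(f"TFR meta is missing {key!r}")
        for stage, mask in masks.items():
            sub = tfr.power[np.ix_(mask.freq_indices, mask.col_indices)]
            value = float(sub[mask.include].mean())
            rows.append(
                {
                    "participant": meta["participant"],
                    "group": meta["group"],
                    "electrode": meta["electrode"],
                    "region": electrode_region(meta["electrode"]),
                    "hemisphere": electrode_hemisphere(meta["electrode"]),
                    "condition": meta["condition"],
                    "stage": stage,
                    "mrbd_db": value,
                }
            )
    df = pd.DataFrame(rows, columns=MRBD_COLUMNS)
    dup = df.duplicated(subset=MRBD_COLUMNS[:-1])
    if dup.any():
        raise ValueError("duplicate participant/electrode/condition/stage rows")
    return df
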