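"""Fair / sub-potent / contaminated determinations and their scoring.

Predicted per-alcohol concentrations feed a fixed decision tree: a sample is
``contaminated`` if any contaminant alcohol (methanol, 1-propanol) reaches the
contaminant threshold; otherwise ``subpotent`` if the total approved alcohol
(ethanol + 2-propanol) is below the potency threshold; otherwise ``fair``.
Contamination takes precedence — the more severe public-health finding wins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np

from .spectra import ALCOHOLS, APPROVED, CONTAMINANTS, Spectrum

LABELS = ("fair", "subpotent", "contaminated")


@dataclass(frozen=True)
class ScreeningPolicy:
    """Decision thresholds in % v/v.

    The default potency floor of 60% total approved alcohol follows the CDC
    minimum for effective hand rubs; the WHO preset instead screens against
    the 80/75% formulation targets.  The contaminant threshold defaults to 5%,
    the upper edge of the method's per-alcohol detection-limit band (1-5%).
    """

    potency_threshold: float = 60.0
    contaminant_threshold: float = 5.0
    approved: Tuple[str, ...] = APPROVED
    contaminants: Tuple[str, ...] = CONTAMINANTS

    def __post_init__(self) -> None:
        if self.potency_threshold <= 0 or self.contaminant_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if not (1.0 <= self.contaminant_threshold <= 5.0):
            raise ValueError("contaminant_threshold must lie in the 1-5% v/v detection band")

    @classmethod
    def cdc(cls) -> "ScreeningPolicy":
        return cls(potency_threshold=60.0)

    @classmethod
    def who(cls) -> "ScreeningPolicy":
        return cls(potency_threshold=75.0)


@dataclass
class Determination:
    sample_id: str
    label: str
    predicted: Dict[str, float]
    rule: str


def determine(predicted: Mapping[str, float], policy: Optional[ScreeningPolicy] = None,
              sample_id: str = "") -> Determination:
    """Apply the decision tree to one sample's predicted fractions.

    Negative predictions are clamped to zero.  All four alcohols must be
    present in ``predicted``.
    """
    policy = policy or ScreeningPolicy()
    missing = [a for a in ALCOHOLS if a not in predicted]
    if missing:
        raise KeyError(f"missing predictions for {missing}")
    clamped = {a: max(0.0, float(predicted[a])) for a in ALCOHOLS}
    hot = [c for c in policy.contaminants if clamped[c] >= policy.contaminant_threshold]
    if hot:
        rule = ", ".join(f"{c} {clamped[c]:.1f} >= {policy.contaminant_threshold:g}% v/v" for c in hot)
        return Determination(sample_id, "contaminated", clamped, rule)
    approved_total = sum(clamped[a] for a in policy.approved)
    if approved_total < policy.potency_threshold:
        rule = f"approved total {approved_total:.1f} < {policy.potency_threshold:g}% v/v"
        return Determination(sample_id, "subpotent", clamped, rule)
    return Determination(sample_id, "fair", clamped,
                         f"approved total {approved_total:.1f}% v/v, no contaminant at threshold")


@dataclass
class ConfusionReport:
    labels: Tuple[str, ...]
    matrix: np.ndarray  # rows = truth, columns = predicted
    accuracy: float
    per_class_recall: Dict[str, float]

    @property
    def n_samples(self) -> int:
        return int(self.matrix.sum())


def score(dets: Sequence[Determination], truth: Sequence[str]) -> ConfusionReport:
    """3x3 confusion matrix (truth rows x predicted columns) and accuracy."""
    if len(dets) != len(truth):
        raise ValueError("determinations and truth labels must align")
    idx = {lab: i for i, lab in enumerate(LABELS)}
    mat = np.zeros((3, 3), dtype=int)
    for d, t in zip(dets, truth):
        if t not in idx:
            raise ValueError(f"truth label {t!r} outside {LABELS}")
        if d.label not in idx:
            raise ValueError(f"predicted label {d.label!r} outside {LABELS}")
        mat[idx[t], idx[d.label]] += 1
    n = mat.sum()
    acc = float(np.trace(mat) / n) if n else 0.0
    recall = {}
    for lab in LABELS:
        row = mat[idx[lab]]
        recall[lab] = float(row[idx[lab]] / row.sum()) if row.sum() else float("nan")
    return ConfusionReport(labels=LABELS, matrix=mat, accuracy=acc, per_class_recall=recall)


# ---------------------------------------------------------------------------
# limit of detection

#: band windows (cm^-1) used to detect each contaminant in preprocessed
#: scaled-subtracted spectra: the methanol C-O stretch and the 1-propanol C-O
#: stretch, both free of overlap from the approved-alcohol bands
CONTAMINANT_WINDOWS: Dict[str, Tuple[float, float]] = {
    "methanol": (1022.0, 1040.0),
    "propan1ol": (958.0, 978.0),
}


def _window_slice(s: Spectrum, window: Tuple[float, float]) -> Tuple[np.ndarray, np.ndarray]:
    nu = s.grid.values
    mask = (nu >= window[0]) & (nu <= window[1])
    return nu[mask], s.intensities[mask]


def _matched_signal(y: np.ndarray, background: np.ndarray, profile: np.ndarray) -> float:
    """Matched-filter band amplitude after scaled blank subtraction.

    The background (mean blank window) is fitted to the replicate by a single
    scale factor, cancelling both the shape and the multiplicative jitter of
    the approved-alcohol band tail; the residual is correlated with the
    unit-norm expected band profile — the maximum-SNR linear statistic for a
    band of known shape in white noise.
    """
    denom = float(background @ background)
    alpha = float(y @ background) / denom if denom > 0 else 0.0
    return float((y - alpha * background) @ profile)


def estimate_lod(
    series: Mapping[float, Sequence[Spectrum]],
    window: Tuple[float, float],
    snr_factor: float = 3.0,
    min_fraction: float = 0.95,
    band_fwhm: float = 16.0,
) -> float:
    """Band-window SNR detection limit from a dilution series.

    ``series`` maps contaminant concentration (% v/v) to replicate
    preprocessed spectra; it must include 0% blanks, whose mean window shape
    serves as the background and whose replicate scatter sets the noise
    scale.  A concentration is detected when the blank-corrected band signal
    exceeds the blank mean by ``snr_factor`` blank standard deviations in at
    least ``min_fraction`` of replicates.  Returns the lowest detected tested
    concentration (inf if none).
    """
    if 0.0 not in series or len(series[0.0]) < 2:
        raise ValueError("series must include >= 2 blank (0%) replicates")
    x, _ = _window_slice(series[0.0][0], window)
    center = 0.5 * (window[0] + window[1])
    g = band_fwhm / 2.0
    profile = g * g / ((x - center) ** 2 + g * g)
    profile = profile / np.linalg.norm(profile)
    background = np.mean([_window_slice(s, window)[1] for s in series[0.0]], axis=0)

    blank_signals = np.array([
        _matched_signal(_window_slice(s, window)[1], background, profile)
        for s in series[0.0]
    ])
    blank_mean, blank_sd = float(blank_signals.mean()), float(blank_signals.std(ddof=1))
    threshold = blank_mean + snr_factor * blank_sd
    detected = []
    for conc in sorted(series):
        if conc <= 0:
            continue
        signals = np.array([
            _matched_signal(_window_slice(s, window)[1], background, profile)
            for s in series[conc]
        ])
        frac = float(np.mean(signals > threshold))
        if frac >= min_fraction:
            detected.append(conc)
    return float(min(detected)) if detected else float("inf")
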