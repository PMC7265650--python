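"""Quality filtering, transformation, imputation and feature selection.

The fixed preprocessing order for quantified omics matrices is

    log2 transform  ->  detection filter  ->  downshifted-normal imputation

optionally followed by most-variable feature selection for expression data.
Missing values in metabolomics are treated as left-censored (below the
detection limit), so imputation draws each missing entry from a normal
distribution shifted below the feature's observed distribution — the
Perseus-style "imputation from a downshifted normal" with the documented
defaults width 0.3 and downshift 1.8 (in units of the feature's observed
standard deviation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .omics import OmicsError, OmicsMatrix

logger = logging.getLogger(__name__)


class PipelineStateError(RuntimeError):
    """Raised when preprocessing stages are run out of order."""


@dataclass
class FilterReport:
    min_fraction: float
    kept: list[str]
    dropped: list[str]

    def to_dict(self) -> dict:
        return {"min_fraction": self.min_fraction, "kept": self.kept, "dropped": self.dropped}


def log2_transform(matrix: OmicsMatrix) -> OmicsMatrix:
    """Log2-transform observed entries; mask unchanged.

    Raises for non-positive observed values (naming the offending feature
    and sample) and if the matrix is already log-transformed.
    """
    if matrix.log_transformed:
        raise PipelineStateError("matrix is already log2-transformed")
    bad = (matrix.values <= 0) & matrix.observed_mask
    if bad.any():
        fi, si = np.argwhere(bad)[0]
        raise OmicsError(
            f"non-positive observed value {matrix.values[fi, si]!r} at feature "
            f"{matrix.feature_ids[fi]!r}, sample {matrix.sample_ids[si]!r}"
        )
    out = matrix.copy(log_transformed=True)
    with np.errstate(invalid="ignore"):
        out.values = np.where(matrix.observed_mask, np.log2(matrix.values), np.nan)
    return out


def filter_detection(matrix: OmicsMatrix, min_fraction: float = 0.75
                     ) -> tuple[OmicsMatrix, FilterReport]:
    """Keep features observed in at least ``min_fraction`` of samples (inclusive).

    Feature order is preserved.  An empty result warns rather than raising.
    """
    if not (0.0 < min_fraction <= 1.0):
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    frac = matrix.observed_fraction()
    keep = frac >= min_fraction - 1e-12
    kept = [f for f, k in zip(matrix.feature_ids, keep) if k]
    dropped = [f for f, k in zip(matrix.feature_ids, keep) if not k]
    if not kept:
        logger.warning("detection filter at %.2f removed every feature", min_fraction)
        out = OmicsMatrix(kept, list(matrix.sample_ids),
                          np.empty((0, matrix.n_samples)),
                          np.empty((0, matrix.n_samples), dtype=bool),
                          log_transformed=matrix.log_transformed)
    else:
        out = matrix.subset_features(kept)
    return out, FilterReport(min_fraction, kept, dropped)


def impute_downshifted_normal(matrix: OmicsMatrix, width: float = 0.3,
                              shift: float = 1.8, seed: int = 0,
                              per: str = "feature") -> OmicsMatrix:
    """Impute missing entries from a downshifted normal.

    With the default ``per="feature"``, each missing entry of feature f is
    drawn from ``Normal(mean_f - shift * sd_f, (width * sd_f)^2)`` where
    mean_f and sd_f come from f's observed values only — observed values
    are inputs, never targets, of imputation.  ``per="sample"`` computes
    the statistics from each sample's observed values instead (the other
    convention some preprocessing tools use).  Deterministic given
    ``seed``.
    """
    if per not in ("feature", "sample"):
        raise ValueError(f"per must be 'feature' or 'sample', got {per!r}")
    if not matrix.log_transformed:
        raise PipelineStateError("impute on the log2 scale: run log2_transform first")
    values = matrix.values if per == "feature" else matrix.values.T
    mask = matrix.observed_mask if per == "feature" else matrix.observed_mask.T
    labels = matrix.feature_ids if per == "feature" else matrix.sample_ids
    too_few = mask.sum(axis=1) < 2
    if too_few.any():
        bad = [f for f, t in zip(labels, too_few) if t]
        raise OmicsError(
            f"cannot estimate sd for {per}s with < 2 observed values: {bad[:5]}")
    out = matrix.copy()
    if matrix.observed_mask.all():
        return out
    target = out.values if per == "feature" else out.values.T
    rng = np.random.default_rng(seed)
    for i in range(values.shape[0]):
        miss = ~mask[i]
        if not miss.any():
            continue
        obs = values[i, mask[i]]
        mu, sd = float(obs.mean()), float(obs.std(ddof=1))
        target[i, miss] = rng.normal(mu - shift * sd, width * sd, size=int(miss.sum()))
    out.observed_mask = np.ones_like(matrix.observed_mask)
    return out


def select_most_variable(matrix: OmicsMatrix, k: int = 2000) -> OmicsMatrix:
    """Keep the k features with the largest sample standard deviation.

    Ties are broken in favour of the lexicographically smaller feature id;
    k larger than the feature count clamps with a warning.  The result is
    ordered by descending sd.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not matrix.fully_observed:
        raise PipelineStateError("feature selection requires a fully observed matrix")
    if k > matrix.n_features:
        logger.warning("k=%d exceeds feature count %d; clamping", k, matrix.n_features)
        k = matrix.n_features
    sds = matrix.values.std(axis=1, ddof=1)
    order = sorted(range(matrix.n_features), key=lambda i: (-sds[i], matrix.feature_ids[i]))
    keep = [matrix.feature_ids[i] for i in order[:k]]
    return matrix.subset_features(keep)
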