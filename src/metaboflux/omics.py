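"""Feature x sample quantification matrices and sample annotations.

:class:`OmicsMatrix` is the substrate of every pipeline stage: a real-valued
feature x sample matrix (metabolite abundances or gene expression) together
with an observation mask marking entries below the detection limit, and a
flag recording whether values are already on the log2 scale.

Missing entries are stored as ``nan`` and simultaneously flagged ``False``
in ``observed_mask``; the mask, not the sentinel, is authoritative.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class OmicsError(ValueError):
    """Domain error raised for invalid omics-matrix operations."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise OmicsError(f"duplicate {what} ids: {dups[:5]}")


@dataclass
class OmicsMatrix:
    """Quantification matrix with missingness mask.

    Parameters
    ----------
    feature_ids : ordered unique feature identifiers (rows).
    sample_ids : ordered unique sample identifiers (columns).
    values : float array, shape (n_features, n_samples); entries where
        ``observed_mask`` is False hold ``nan``.
    observed_mask : boolean array, same shape; True = measured.
    log_transformed : whether values are on the log2 scale.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    observed_mask: np.ndarray = None  # type: ignore[assignment]
    log_transformed: bool = False

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise OmicsError("values must be a 2-D array")
        if self.observed_mask is None:
            self.observed_mask = ~np.isnan(self.values)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        nf, ns = self.values.shape
        if nf != len(self.feature_ids) or ns != len(self.sample_ids):
            raise OmicsError(
                f"shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if self.observed_mask.shape != self.values.shape:
            raise OmicsError("observed_mask shape differs from values shape")
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")
        # sentinel discipline: unobserved entries are nan, never silently numeric
        vals = self.values.copy()
        vals[~self.observed_mask] = np.nan
        self.values = vals

    # ------------------------------------------------------------------
    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def fully_observed(self) -> bool:
        return bool(self.observed_mask.all())

    def observed_fraction(self) -> np.ndarray:
        """Per-feature fraction of observed samples."""
        return self.observed_mask.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, log_transformed: bool = False) -> "OmicsMatrix":
        return cls(
            feature_ids=list(map(str, df.index)),
            sample_ids=list(map(str, df.columns)),
            values=df.to_numpy(dtype=float),
            observed_mask=~df.isna().to_numpy(),
            log_transformed=log_transformed,
        )

    def copy(self, **overrides) -> "OmicsMatrix":
        kwargs = dict(
            feature_ids=list(self.feature_ids),
            sample_ids=list(self.sample_ids),
            values=self.values.copy(),
            observed_mask=self.observed_mask.copy(),
            log_transformed=self.log_transformed,
        )
        kwargs.update(overrides)
        return OmicsMatrix(**kwargs)

    def subset_features(self, keep: Iterable[str]) -> "OmicsMatrix":
        keep = list(keep)
        index = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in keep if f not in index]
        if missing:
            raise OmicsError(f"unknown features: {missing[:5]}")
        rows = [index[f] for f in keep]
        return OmicsMatrix(
            feature_ids=keep,
            sample_ids=list(self.sample_ids),
            values=self.values[rows],
            observed_mask=self.observed_mask[rows],
            log_transformed=self.log_transformed,
        )

    def feature_values(self, feature_id: str) -> np.ndarray:
        try:
            row = self.feature_ids.index(feature_id)
        except ValueError:
            raise OmicsError(f"unknown feature {feature_id!r}") from None
        return self.values[row]

    # ------------------------------------------------------------------
    def write_tsv(self, path) -> None:
        """Write features-as-rows TSV; unobserved entries become empty cells."""
        self.to_frame().to_csv(path, sep="\t", na_rep="", index_label="feature_id")

    @classmethod
    def read_tsv(cls, path, zero_as_missing: bool = False,
                 log_transformed: bool = False) -> "OmicsMatrix":
        """Read a features-as-rows TSV.

        Empty cells and ``NA`` are treated as missing.  Zeros are observed
        values by default; ``zero_as_missing`` flips this for metabolomics
        dialects that encode below-detection as 0.
        """
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
        if zero_as_missing:
            df = df.where(df != 0.0, np.nan)
        return cls.from_frame(df, log_transformed=log_transformed)


@dataclass
class SampleAnnotation:
    """Per-sample clinical annotation: group label, survival, covariates.

    ``covariates`` holds named categorical/ordinal clinical fields (tumor
    stage T, node category N, grade G) as a DataFrame indexed by sample id.
    """

    sample_ids: list[str]
    group: pd.Series  # categorical, indexed by sample id
    survival_time: pd.Series | None = None  # months >= 0
    event: pd.Series | None = None  # boolean
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.sample_ids, "sample")
        self.group = pd.Series(self.group).reindex(self.sample_ids)
        if (self.event is not None) != (self.survival_time is not None):
            raise OmicsError("survival_time and event must be given together")
        if self.survival_time is not None:
            self.survival_time = pd.Series(self.survival_time).reindex(self.sample_ids)
            self.event = pd.Series(self.event).reindex(self.sample_ids).astype(bool)
            if (self.survival_time < 0).any():
                raise OmicsError("survival times must be >= 0")
        if self.covariates is not None:
            self.covariates = self.covariates.reindex(self.sample_ids)

    def groups(self) -> list:
        return sorted(self.group.dropna().unique().tolist())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"group": self.group})
        if self.survival_time is not None:
            df["survival_time"] = self.survival_time
            df["event"] = self.event.astype(int)
        if self.covariates is not None:
            df = df.join(self.covariates)
        df.index.name = "sample_id"
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "SampleAnnotation":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.map(str)
        surv = df["survival_time"] if "survival_time" in df else None
        event = df["event"].astype(bool) if "event" in df else None
        covar_cols = [c for c in df.columns if c not in ("group", "survival_time", "event")]
        return cls(
            sample_ids=list(df.index),
            group=df["group"],
            survival_time=surv,
            event=event,
            covariates=df[covar_cols] if covar_cols else None,
        )
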