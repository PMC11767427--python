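"""Cohort containers, table IO, missingness filtering and BMD staging.

A cohort is an abundance matrix (samples x metabolites, non-negative
concentrations) plus per-sample metadata (gender, BMD stage or per-site
T-score inputs, clinical covariates).  Staging follows the WHO T-score
convention: osteoporosis if any site falls below -2.5, control if every
site is at or above the control threshold (default -1.0), osteopenia in
between.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Ordered disease stages, from healthy reference to overt disease.
STAGES: tuple[str, str, str] = ("control", "osteopenia", "osteoporosis")

#: Cell contents treated as missing in abundance tables.  "<LOD" (below
#: limit of detection) counts as missing, not as zero.
MISSING_TOKENS: tuple[str, ...] = ("", "NA", "NaN", "nan", "<LOD")


@dataclass
class Cohort:
    """Aligned abundance matrix and sample metadata.

    Parameters
    ----------
    abundance
        DataFrame indexed by sample_id, one column per metabolite.
    metadata
        DataFrame indexed by sample_id; may carry ``stage``, ``gender``
        and arbitrary numeric clinical covariates.
    """

    abundance: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.abundance.index.duplicated().any():
            dups = self.abundance.index[self.abundance.index.duplicated()].unique()
            raise ValueError(f"duplicate sample_id(s): {list(dups)}")
        if self.abundance.columns.duplicated().any():
            dups = self.abundance.columns[self.abundance.columns.duplicated()].unique()
            raise ValueError(f"duplicate metabolite id(s): {list(dups)}")
        if not self.abundance.index.equals(self.metadata.index):
            raise ValueError("abundance and metadata sample ids are not aligned")
        if "stage" in self.metadata.columns:
            bad = set(self.metadata["stage"].dropna()) - set(STAGES)
            if bad:
                raise ValueError(f"unknown stage label(s): {sorted(bad)}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.abundance.index

    @property
    def metabolite_ids(self) -> pd.Index:
        return self.abundance.columns

    @property
    def n_samples(self) -> int:
        return len(self.abundance)

    @property
    def n_metabolites(self) -> int:
        return self.abundance.shape[1]

    @property
    def stages(self) -> pd.Series:
        if "stage" not in self.metadata.columns:
            raise KeyError("cohort has no 'stage' column; run assign_stage first")
        return self.metadata["stage"]

    def stage_samples(self, stage: str) -> pd.Index:
        return self.sample_ids[self.stages == stage]

    def subset(self, sample_ids: Sequence) -> "Cohort":
        idx = pd.Index(sample_ids)
        return Cohort(self.abundance.loc[idx].copy(), self.metadata.loc[idx].copy())


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    return pd.read_csv(path, sep=sep, dtype={0: str}, index_col=0,
                       na_values=list(MISSING_TOKENS), keep_default_na=False)


def load_cohort(abundance_path: str | Path, metadata_path: str | Path) -> Cohort:
    """Read abundance and metadata tables and align them on sample_id.

    Samples present in only one of the two tables are dropped with a
    logged warning.  Duplicate sample ids or non-numeric abundance cells
    (other than declared missing tokens) are hard errors naming the
    offending row/column.
    """
    abundance = _read_table(abundance_path)
    metadata = _read_table(metadata_path)

    for name, frame in (("abundance", abundance), ("metadata", metadata)):
        if frame.index.duplicated().any():
            dup = frame.index[frame.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample_id in {name} table: {dup}")

    for col in abundance.columns:
        coerced = pd.to_numeric(abundance[col], errors="coerce")
        bad = abundance[col].notna() & coerced.isna()
        if bad.any():
            row = abundance.index[bad][0]
            raise ValueError(
                f"non-numeric abundance cell at sample {row!r}, metabolite {col!r}: "
                f"{abundance.loc[row, col]!r}"
            )
        abundance[col] = coerced

    common = abundance.index.intersection(metadata.index)
    dropped = set(abundance.index).symmetric_difference(metadata.index)
    if dropped:
        logger.warning("dropping %d sample(s) missing from one table: %s",
                       len(dropped), sorted(dropped))
    if len(common) == 0:
        raise ValueError("no samples shared between abundance and metadata tables")
    order = [s for s in abundance.index if s in set(common)]
    return Cohort(abundance.loc[order], metadata.loc[order])


def filter_missing(
    cohort: Cohort,
    max_missing_fraction: float = 0.20,
    impute: str = "median",
    by_gender: bool = True,
) -> tuple[Cohort, pd.DataFrame]:
    """Drop metabolites with too much missingness, then impute the rest.

    Metabolites missing in strictly more than ``max_missing_fraction`` of
    samples are excluded.  Remaining missing cells are imputed with the
    per-metabolite median (within gender stratum when gender is available
    and ``by_gender``), with ``half_min`` (half the observed minimum, an
    LOD-style fill) and ``none`` as alternatives.

    Returns the filtered cohort and a removal report
    (metabolite_id, missing_fraction, kept).
    """
    if not 0 <= max_missing_fraction < 1:
        raise ValueError("max_missing_fraction must be in [0, 1)")
    if impute not in {"median", "half_min", "none"}:
        raise ValueError(f"unknown imputation mode {impute!r}")

    frac = cohort.abundance.isna().mean(axis=0)
    kept = frac.index[frac <= max_missing_fraction]
    report = pd.DataFrame({
        "metabolite_id": frac.index,
        "missing_fraction": frac.values,
        "kept": (frac <= max_missing_fraction).astype(int).values,
    })
    if len(kept) == 0:
        raise ValueError("missingness filter removed every metabolite")
    dropped = frac.index.difference(kept)
    if len(dropped):
        logger.warning("missingness filter removed %d metabolite(s)", len(dropped))

    abund = cohort.abundance[kept].copy()
    if impute != "none" and abund.isna().any().any():
        strata: list[pd.Index]
        if by_gender and "gender" in cohort.metadata.columns:
            strata = [cohort.sample_ids[cohort.metadata["gender"] == g]
                      for g in cohort.metadata["gender"].unique()]
        else:
            strata = [cohort.sample_ids]
        for idx in strata:
            block = abund.loc[idx]
            if impute == "median":
                fill = block.median(axis=0)
            else:  # half_min
                fill = block.min(axis=0) / 2.0
            abund.loc[idx] = block.fillna(fill)
        # a stratum that is entirely missing for a metabolite falls back
        # to the global fill
        if abund.isna().any().any():
            glob = abund.median(axis=0) if impute == "median" else abund.min(axis=0) / 2.0
            abund = abund.fillna(glob)
    return Cohort(abund, cohort.metadata.copy()), report


@dataclass(frozen=True)
class TScorePanel:
    """One DXA site's BMD measurement with its young-adult reference.

    All three quantities are in g/cm^2; sites are typically lumbar spine
    L1-4, femoral neck and total hip.
    """

    site: str
    measured: float
    young_mean: float
    young_sd: float

    @property
    def t(self) -> float:
        return t_score(self.measured, self.young_mean, self.young_sd)


def t_score(measured: float, young_mean: float, young_sd: float) -> float:
    """T-score: (measured BMD - young-adult mean) / young-adult SD."""
    if not young_sd > 0:
        raise ValueError("young-adult SD must be positive")
    t = (measured - young_mean) / young_sd
    if not np.isfinite(t):
        raise ValueError("non-finite T-score")
    return t


def assign_stage(
    panels_per_sample: Mapping[str, Iterable[TScorePanel]] | Sequence[Iterable[TScorePanel]],
    osteoporosis_threshold: float = -2.5,
    control_threshold: float = -1.0,
) -> pd.Series:
    """Assign each sample to control / osteopenia / osteoporosis.

    A sample is osteoporosis if any site's T-score is below
    ``osteoporosis_threshold``, control if all sites are at or above
    ``control_threshold``, and osteopenia otherwise.  Sites missing their
    young-adult reference are skipped with a warning; a sample with no
    usable site is an error.
    """
    if not osteoporosis_threshold < control_threshold:
        raise ValueError("osteoporosis threshold must be below the control threshold")
    if isinstance(panels_per_sample, Mapping):
        items = list(panels_per_sample.items())
    else:
        items = list(enumerate(panels_per_sample))
    logger.info("staging convention: osteoporosis T < %.2f at any site, control T >= %.2f at all sites",
                osteoporosis_threshold, control_threshold)
    labels = {}
    for sample, panels in items:
        ts = []
        for p in panels:
            try:
                ts.append(p.t)
            except ValueError:
                logger.warning("sample %r site %r skipped: unusable young-adult reference",
                               sample, p.site)
        if not ts:
            raise ValueError(f"sample {sample!r} has no usable BMD site")
        if min(ts) < osteoporosis_threshold:
            labels[sample] = "osteoporosis"
        elif min(ts) >= control_threshold:
            labels[sample] = "control"
        else:
            labels[sample] = "osteopenia"
    return pd.Series(labels, name="stage")
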