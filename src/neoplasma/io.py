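"""Readers and writers for the pipeline's external tables.

The proteomics side speaks the MaxQuant ``proteinGroups.txt`` dialect:
tab-separated, boolean flags encoded as ``"+"``/empty, and an LFQ or iBAQ
value of 0 meaning "not quantified" (MaxQuant never reports a true zero
intensity).  LFQ intensities are log2-transformed on read and kept on the
log2 scale everywhere downstream; iBAQ values stay on the linear scale
because the immunoglobulin analysis takes ratios of them.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_DOLS = (0, 1, 3, 7)
FOLLOWUP_DOLS = (1, 3, 7)

#: MaxQuant flag columns -> our record fields
_FLAG_COLUMNS = {
    "Reverse": "is_reverse",
    "Potential contaminant": "is_contaminant",
    "Only identified by site": "only_modified_site",
}

RECORD_COLUMNS = [
    "protein_group_id",
    "gene_name",
    "is_reverse",
    "is_contaminant",
    "only_modified_site",
    "unique_peptides",
]

META_COLUMNS = ["sample_id", "participant_id", "dol", "sex", "batch", "cohort"]


class FormatError(ValueError):
    """A file does not follow the expected dialect."""


class DesignError(ValueError):
    """Sample metadata violates the paired study design."""


@dataclass
class ProteinQuantMatrix:
    """Proteins x samples quantification matrix.

    Attributes
    ----------
    records : pd.DataFrame
        One row per protein group, columns :data:`RECORD_COLUMNS`, indexed
        by ``protein_group_id``.
    lfq : pd.DataFrame
        log2 LFQ intensities, NaN = not quantified; same index as
        ``records``, one column per sample.
    ibaq : pd.DataFrame or None
        Linear-scale iBAQ values (NaN = not quantified), same shape.
    imputed : bool
        Provenance flag: True once missing entries have been filled in.
        Statistical stages refuse imputed matrices.
    """

    records: pd.DataFrame
    lfq: pd.DataFrame
    ibaq: pd.DataFrame | None = None
    imputed: bool = False

    def __post_init__(self) -> None:
        self.validate()

    @property
    def samples(self) -> list[str]:
        return list(self.lfq.columns)

    @property
    def n_proteins(self) -> int:
        return len(self.records)

    def validate(self) -> None:
        missing = [c for c in RECORD_COLUMNS if c not in self.records.columns]
        if missing:
            raise FormatError(f"records table lacks columns: {missing}")
        if len(self.records) != len(self.lfq):
            raise ValueError(
                f"records ({len(self.records)}) and lfq ({len(self.lfq)}) row counts differ"
            )
        if not self.records.index.equals(self.lfq.index):
            raise ValueError("records and lfq indexes differ")
        if self.records.index.has_duplicates:
            raise ValueError("duplicate protein_group_id values")
        if (self.records["protein_group_id"].astype(str) == "").any():
            raise ValueError("empty protein_group_id")
        vals = self.lfq.to_numpy(float)
        if np.isinf(vals).any():
            raise ValueError("non-finite LFQ values present")
        if self.ibaq is not None:
            if self.ibaq.shape != self.lfq.shape:
                raise ValueError("ibaq shape differs from lfq shape")
            ib = self.ibaq.to_numpy(float)
            if np.nanmin(ib, initial=np.inf) <= 0:
                raise ValueError("iBAQ values must be strictly positive where present")

    def subset_rows(self, mask: np.ndarray | pd.Series) -> "ProteinQuantMatrix":
        return ProteinQuantMatrix(
            records=self.records.loc[mask].copy(),
            lfq=self.lfq.loc[mask].copy(),
            ibaq=None if self.ibaq is None else self.ibaq.loc[mask].copy(),
            imputed=self.imputed,
        )

    def subset_samples(self, samples: Sequence[str]) -> "ProteinQuantMatrix":
        samples = list(samples)
        return ProteinQuantMatrix(
            records=self.records.copy(),
            lfq=self.lfq[samples].copy(),
            ibaq=None if self.ibaq is None else self.ibaq[samples].copy(),
            imputed=self.imputed,
        )

    def copy(self) -> "ProteinQuantMatrix":
        return ProteinQuantMatrix(
            records=self.records.copy(),
            lfq=self.lfq.copy(),
            ibaq=None if self.ibaq is None else self.ibaq.copy(),
            imputed=self.imputed,
        )


@dataclass
class RnaCountMatrix:
    """Genes x samples integer count matrix."""

    counts: pd.DataFrame  # index = gene ids, columns = sample ids

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            as_float = self.counts.to_numpy(float)
            if not np.all(np.isfinite(as_float)) or np.any(as_float != np.round(as_float)):
                raise ValueError("RNA counts must be non-negative integers")
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("RNA counts must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


def validate_sample_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate the paired design: one DOL0 sample per participant plus at
    most one follow-up sample at exactly one of DOL 1, 3 or 7.

    Returns the validated frame (dol coerced to int); raises
    :class:`DesignError` naming offending participants otherwise.
    """
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"sample metadata lacks columns: {missing}")
    meta = meta.copy()
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise DesignError(f"duplicate sample_id values: {dups}")
    try:
        meta["dol"] = meta["dol"].astype(int)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-integer dol values: {exc}") from exc
    bad_dol = sorted(set(meta["dol"]) - set(VALID_DOLS))
    if bad_dol:
        raise DesignError(f"dol values outside {VALID_DOLS}: {bad_dol}")
    bad_sex = sorted(set(meta["sex"].astype(str)) - {"F", "M"})
    if bad_sex:
        raise DesignError(f"sex values outside {{F, M}}: {bad_sex}")

    offenders: list[str] = []
    for pid, grp in meta.groupby("participant_id"):
        n_base = int((grp["dol"] == 0).sum())
        followups = grp.loc[grp["dol"] != 0, "dol"].tolist()
        if n_base != 1 or len(followups) > 1:
            offenders.append(str(pid))
    if offenders:
        raise DesignError(
            "participants violating the one-DOL0-plus-one-follow-up design: "
            + ", ".join(sorted(offenders))
        )
    return meta


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    """Read and validate a sample metadata table (CSV or TSV by extension)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    meta = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "participant_id": str})
    return validate_sample_meta(meta)


def read_protein_groups(
    path: str | Path,
    sample_map: Mapping[str, str],
) -> ProteinQuantMatrix:
    """Read a MaxQuant-style ``proteinGroups.txt``.

    Parameters
    ----------
    sample_map : mapping
        Raw sample-column label (the ``<s>`` in ``LFQ intensity <s>``) to
        the sample_id used in the metadata.  Mapping is explicit: MaxQuant
        embeds raw-file names and no fuzzy matching is attempted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")

    for col in ("Protein IDs",):
        if col not in df.columns:
            raise FormatError(f"mandatory column missing: {col!r}")
    lfq_cols = {c[len("LFQ intensity "):]: c for c in df.columns if c.startswith("LFQ intensity ")}
    if not lfq_cols:
        raise FormatError("no 'LFQ intensity <sample>' columns found")
    ibaq_cols = {
        c[len("iBAQ "):]: c
        for c in df.columns
        if c.startswith("iBAQ ") and c != "iBAQ peptides"
    }

    unknown = [raw for raw in sample_map if raw not in lfq_cols]
    if unknown:
        raise FormatError(f"sample_map labels without LFQ columns: {unknown}")
    ids = list(sample_map.values())
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate sample IDs in sample_map: {ids}")

    records = pd.DataFrame(
        {
            "protein_group_id": df["Protein IDs"],
            "gene_name": df.get("Gene names", pd.Series([""] * len(df))),
            "is_reverse": (df.get("Reverse", "") == "+") if "Reverse" in df else False,
            "is_contaminant": (df.get("Potential contaminant", "") == "+")
            if "Potential contaminant" in df
            else False,
            "only_modified_site": (df.get("Only identified by site", "") == "+")
            if "Only identified by site" in df
            else False,
            "unique_peptides": pd.to_numeric(
                df.get("Razor + unique peptides", pd.Series(["0"] * len(df))),
                errors="coerce",
            )
            .fillna(0)
            .astype(int),
        }
    )
    if records["protein_group_id"].duplicated().any():
        raise ValueError("duplicate Protein IDs rows")
    records.index = pd.Index(records["protein_group_id"], name="protein_group_id")

    def _quant_block(colmap: Mapping[str, str]) -> pd.DataFrame:
        data = {}
        for raw, sid in sample_map.items():
            vals = pd.to_numeric(df[colmap[raw]], errors="coerce").to_numpy(float)
            vals[vals == 0] = np.nan  # MaxQuant 0 == not quantified
            data[sid] = vals
        return pd.DataFrame(data, index=records.index)

    lfq = np.log2(_quant_block(lfq_cols))
    ibaq = None
    if ibaq_cols and all(raw in ibaq_cols for raw in sample_map):
        ibaq = _quant_block(ibaq_cols)
        if ibaq.isna().all().all():
            ibaq = None
    return ProteinQuantMatrix(records=records, lfq=lfq, ibaq=ibaq)


def read_rna_counts(
    path: str | Path,
    drop_genes: Iterable[str] = (),
    min_count: int = 10,
    min_samples_below: int = 9,
) -> RnaCountMatrix:
    """Read a genes x samples count TSV and apply low-count / pattern filters.

    A gene is removed when its count is below ``min_count`` in at least
    ``min_samples_below`` samples (default: fewer than 10 counts in nine or
    more samples), or when its ID matches any of the ``drop_genes`` regex
    patterns (e.g. globins).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    as_float = df.to_numpy(float)
    if np.any(~np.isfinite(as_float)) or np.any(as_float != np.round(as_float)):
        raise ValueError("RNA count matrix contains non-integer values")
    df = df.astype(np.int64)

    patterns = [re.compile(p) for p in drop_genes]
    if patterns:
        keep = [g for g in df.index if not any(p.fullmatch(str(g)) for p in patterns)]
        df = df.loc[keep]
    low = (df.to_numpy() < min_count).sum(axis=1)
    df = df.loc[low < min_samples_below]
    return RnaCountMatrix(counts=df)


def write_results_table(result, path: str | Path) -> None:
    """Write any result object exposing ``to_frame()`` (or a DataFrame) as a
    TSV: one row per protein/gene, stable column order, missing values as
    empty strings, floats at >= 9 significant digits so q-values round-trip.
    """
    frame = result.to_frame() if hasattr(result, "to_frame") else result
    if not isinstance(frame, pd.DataFrame):
        raise TypeError(f"cannot serialize {type(result).__name__}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False, float_format="%.9g", na_rep="")


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
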