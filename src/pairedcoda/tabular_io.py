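"""Count-table and study-metadata I/O.

Reads and writes taxon-by-sample count tables (TSV with an optional
Greengenes-style ``lineage`` column), per-sample study metadata (CSV),
aggregates counts to higher taxonomic ranks and validates the paired
before/after design.

The central container is :class:`AbundanceTable`: a taxa x samples matrix of
non-negative integer read counts plus optional 7-rank prefixed lineage
strings (``k__;p__;c__;o__;f__;g__;s__``).  An empty rank token (e.g. ``g__``)
means the read could not be classified at that rank; aggregation pools such
rows under ``<parent>_unclassified`` where ``<parent>`` is the nearest
classified ancestor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

RANKS = ["kingdom", "phylum", "class", "order", "family", "genus", "species"]
RANK_PREFIXES = ["k__", "p__", "c__", "o__", "f__", "g__", "s__"]

GROUPS = ("intervention", "control")
TIMEPOINTS = ("before", "after")


# ---------------------------------------------------------------------------
# AbundanceTable
# ---------------------------------------------------------------------------

@dataclass
class AbundanceTable:
    """Taxa x samples non-negative integer counts plus optional lineages.

    Invariants enforced at construction: unique taxon and sample ids,
    all counts >= 0, and every sample column sum > 0.
    """

    counts: pd.DataFrame
    lineages: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.duplicated().any():
            dup = counts.index[counts.index.duplicated()][0]
            raise ValueError(f"duplicate taxon id: {dup!r}")
        if counts.columns.duplicated().any():
            dup = counts.columns[counts.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("counts must be numeric")
        if (arr < 0).any():
            ti, si = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at taxon {counts.index[ti]!r}, "
                f"sample {counts.columns[si]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            ti, si = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise ValueError(
                f"non-integer count at taxon {counts.index[ti]!r}, "
                f"sample {counts.columns[si]!r}"
            )
        self.counts = counts.astype(np.int64)
        colsum = self.counts.sum(axis=0)
        if (colsum == 0).any():
            empty = colsum.index[colsum == 0][0]
            raise ValueError(f"sample {empty!r} has zero total count")
        if self.lineages is not None:
            self.lineages = self.lineages.reindex(self.counts.index)

    # -- convenience -------------------------------------------------------

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def depths(self) -> pd.Series:
        """Per-sample total read counts."""
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample closure of the counts (columns sum to 1)."""
        return self.counts / self.counts.sum(axis=0)

    def subset_samples(self, sample_ids: Iterable[str]) -> "AbundanceTable":
        ids = list(sample_ids)
        missing = set(ids) - set(self.counts.columns)
        if missing:
            raise KeyError(f"samples not in table: {sorted(missing)}")
        return AbundanceTable(self.counts[ids].copy(), self.lineages)

    def subset_taxa(self, taxon_ids: Iterable[str]) -> "AbundanceTable":
        ids = list(taxon_ids)
        lin = self.lineages.loc[ids] if self.lineages is not None else None
        return AbundanceTable(self.counts.loc[ids].copy(), lin)

    def equals(self, other: "AbundanceTable") -> bool:
        same_counts = self.counts.equals(other.counts)
        if self.lineages is None and other.lineages is None:
            return same_counts
        if (self.lineages is None) != (other.lineages is None):
            return False
        return same_counts and self.lineages.equals(other.lineages)


def read_abundance_table(path: str | Path) -> AbundanceTable:
    """Read a TSV count table (taxa rows, sample columns, optional final
    ``lineage`` column).  Duplicated headers and negative or non-numeric
    counts are hard errors naming the offending cell.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    body = header[1:]
    seen: set[str] = set()
    for col in body:
        if col in seen:
            raise ValueError(f"duplicate sample id in header: {col!r}")
        seen.add(col)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    lineages = None
    if "lineage" in df.columns:
        lineages = df.pop("lineage")
        lineages.name = "lineage"
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"non-numeric count at taxon {df.index[bad[0]]!r}, "
            f"sample {df.columns[bad[1]]!r}: {df.iat[bad[0], bad[1]]!r}"
        )
    return AbundanceTable(numeric, lineages)


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    """Write the table as TSV; lineages (if present) go in a final column."""
    out = table.counts.copy()
    out.index.name = out.index.name or "taxon_id"
    if table.lineages is not None:
        out["lineage"] = table.lineages
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Lineage handling / rank aggregation
# ---------------------------------------------------------------------------

def _parse_lineage(lineage: str) -> list[str]:
    """Split a Greengenes-style lineage into 7 rank tokens (prefix removed;
    missing or empty tokens become "")."""
    tokens = [""] * len(RANKS)
    if not isinstance(lineage, str):
        return tokens
    for part in lineage.split(";"):
        part = part.strip()
        for i, prefix in enumerate(RANK_PREFIXES):
            if part.startswith(prefix):
                tokens[i] = part[len(prefix):].strip()
                break
    return tokens


def rank_label(lineage: str, rank: str) -> str:
    """Label of ``lineage`` at ``rank``; unclassified ranks pool under the
    nearest classified ancestor as ``<parent>_unclassified``."""
    if rank not in RANKS:
        raise ValueError(
            f"unknown rank {rank!r}; expected one of {RANKS}"
        )
    idx = RANKS.index(rank)
    tokens = _parse_lineage(lineage)
    if tokens[idx]:
        return tokens[idx]
    for j in range(idx - 1, -1, -1):
        if tokens[j]:
            return f"{tokens[j]}_unclassified"
    return "unclassified"


def aggregate_to_rank(table: AbundanceTable, rank: str) -> AbundanceTable:
    """Sum counts over all taxa sharing a label at ``rank``.

    Per-sample column sums are conserved exactly.  Requires lineages.
    """
    if table.lineages is None:
        raise ValueError("table has no lineages; cannot aggregate by rank")
    labels = table.lineages.map(lambda s: rank_label(s, rank))
    idx = RANKS.index(rank)
    grouped = table.counts.groupby(labels.values, sort=False).sum()
    grouped.index.name = "taxon_id"
    # truncated lineage for each aggregated label (first member's prefix)
    trunc = {}
    for taxon, lab in labels.items():
        if lab in trunc:
            continue
        tokens = _parse_lineage(table.lineages[taxon])
        trunc[lab] = ";".join(
            RANK_PREFIXES[i] + tokens[i] for i in range(idx + 1)
        )
    lineages = pd.Series({lab: trunc[lab] for lab in grouped.index},
                         name="lineage")
    return AbundanceTable(grouped, lineages)


# ---------------------------------------------------------------------------
# StudyDesign
# ---------------------------------------------------------------------------

REQUIRED_DESIGN_COLUMNS = ["sample_id", "subject_id", "group", "timepoint"]
OPTIONAL_DESIGN_COLUMNS = ["age", "gender", "bmi", "weight", "meals_per_week"]


@dataclass
class StudyDesign:
    """Per-sample metadata: subject pairing, group and timepoint factors plus
    numeric covariates (age, BMI, weight, meals per week) and gender."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in REQUIRED_DESIGN_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"metadata missing required column(s): {missing}")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample id in metadata: {dup!r}")
        bad_group = set(df["group"]) - set(GROUPS)
        if bad_group:
            raise ValueError(
                f"unknown group value(s) {sorted(bad_group)}; expected {GROUPS}"
            )
        bad_tp = set(df["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise ValueError(
                f"unknown timepoint value(s) {sorted(bad_tp)}; "
                f"expected {TIMEPOINTS}"
            )
        multi = df.groupby("subject_id")["group"].nunique()
        if (multi > 1).any():
            subj = multi.index[multi > 1][0]
            raise ValueError(f"subject {subj!r} assigned to more than one group")
        self.frame = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def sample_for(self, subject: str, timepoint: str) -> Optional[str]:
        df = self.frame
        hit = df[(df["subject_id"] == subject) & (df["timepoint"] == timepoint)]
        if len(hit) == 0:
            return None
        return hit["sample_id"].iloc[0]

    def subjects(self, group: str | None = None) -> list[str]:
        df = self.frame
        if group is not None:
            df = df[df["group"] == group]
        return list(dict.fromkeys(df["subject_id"]))

    def group_of(self, subject: str) -> str:
        df = self.frame
        return df.loc[df["subject_id"] == subject, "group"].iloc[0]

    def sample_attribute(self, column: str) -> pd.Series:
        """Series of ``column`` indexed by sample_id."""
        return self.frame.set_index("sample_id")[column]

    def subject_covariates(self) -> pd.DataFrame:
        """One row per subject with group and the covariate columns."""
        cols = ["subject_id", "group"] + [
            c for c in OPTIONAL_DESIGN_COLUMNS if c in self.frame.columns
        ]
        return (self.frame[cols].drop_duplicates("subject_id")
                .set_index("subject_id"))


def read_study_design(path: str | Path) -> StudyDesign:
    """Read per-sample metadata from CSV."""
    return StudyDesign(pd.read_csv(path))


def write_study_design(design: StudyDesign, path: str | Path) -> None:
    design.frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Pairing validation
# ---------------------------------------------------------------------------

@dataclass
class PairingReport:
    """Outcome of pairing/QC validation.

    ``complete_pairs`` maps subject -> (before_sample, after_sample) for every
    subject usable in paired analyses.  Exclusion is symmetric: a sample
    failing depth QC removes its partner too.
    """

    complete_pairs: dict[str, tuple[str, str]]
    incomplete_subjects: dict[str, list[str]]
    low_depth_samples: list[str]
    excluded_subjects: list[str]
    missing_in_table: list[str]
    subjects_per_group: dict[str, int]
    min_depth: int = 0
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "complete_pairs": {
                s: list(p) for s, p in self.complete_pairs.items()
            },
            "incomplete_subjects": self.incomplete_subjects,
            "low_depth_samples": self.low_depth_samples,
            "excluded_subjects": self.excluded_subjects,
            "missing_in_table": self.missing_in_table,
            "subjects_per_group": self.subjects_per_group,
            "min_depth": self.min_depth,
            "notes": self.notes,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    def paired_samples(self, design: StudyDesign,
                       group: str | None = None) -> list[str]:
        """Sample ids (before then after per subject) of complete pairs,
        optionally restricted to one group."""
        out: list[str] = []
        for subj, (b, a) in self.complete_pairs.items():
            if group is not None and design.group_of(subj) != group:
                continue
            out.extend([b, a])
        return out


def validate_pairing(design: StudyDesign, table: AbundanceTable,
                     min_depth: int = 1000) -> PairingReport:
    """Check the paired design against the count table.

    A sample below ``min_depth`` reads is excluded along with its paired
    sample; subjects with only one timepoint are flagged incomplete.  Samples
    present in the metadata but absent from the table are listed (not fatal).
    """
    depths = table.depths()
    in_table = set(table.sample_ids)
    missing = [s for s in design.sample_ids if s not in in_table]
    low_depth = [
        s for s in design.sample_ids
        if s in in_table and depths[s] < min_depth
    ]

    complete: dict[str, tuple[str, str]] = {}
    incomplete: dict[str, list[str]] = {}
    excluded: list[str] = []
    notes: list[str] = []
    for subj in design.subjects():
        before = design.sample_for(subj, "before")
        after = design.sample_for(subj, "after")
        present = [
            tp for tp, s in (("before", before), ("after", after))
            if s is not None and s in in_table
        ]
        if len(present) < 2:
            incomplete[subj] = present
            continue
        if before in low_depth or after in low_depth:
            excluded.append(subj)
            bad = before if before in low_depth else after
            notes.append(
                f"subject {subj}: sample {bad} below {min_depth} reads; "
                "pair excluded"
            )
            continue
        complete[subj] = (before, after)

    per_group = {g: 0 for g in GROUPS}
    for subj in complete:
        per_group[design.group_of(subj)] += 1
    return PairingReport(
        complete_pairs=complete,
        incomplete_subjects=incomplete,
        low_depth_samples=low_depth,
        excluded_subjects=excluded,
        missing_in_table=missing,
        subjects_per_group=per_group,
        min_depth=min_depth,
        notes=notes,
    )
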