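"""Clonotype table input/output and clonotype-level preprocessing.

A *clonotype* is the unit of repertoire diversity: all sequenced molecules
sharing the same V, (D) and J gene segments and the same CDR3 nucleotide
sequence.  This module reads clonotype tables as emitted by the common
MIXCR/VDJtools processing chain, collapses raw rows into clonotypes under
that identity rule, removes non-functional rearrangements (CDR3 containing a
stop codon ``*`` or a frameshift ``_``), and provides the small sequence
utilities (CDR3 translation, IMGT segment-name normalisation) the rest of
the package relies on.

Two table dialects are supported:

``vdjtools``
    columns ``count  freq  cdr3nt  cdr3aa  v  d  j`` (the default), and
``mixcr``
    raw MIXCR export columns (``cloneCount``, ``cloneFraction``,
    ``nSeqCDR3``, ``aaSeqCDR3``, ``allVHitsWithScore`` ...); multi-hit
    segment fields keep the best hit and scores are stripped.

Sample metadata (donor, CD4/CD8 subset, TRA/TRB chain, case/control
condition) is never guessed from file names; it comes from an explicit
YAML/JSON manifest (one entry per sample) read by :func:`read_manifest`.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import yaml
from Bio.Seq import Seq

log = logging.getLogger(__name__)

#: Canonical token for an absent D segment (TRA chains, or undetected D).
MISSING_SEGMENT = "."

_MISSING_TOKENS = {".", "", "na", "nan", "none", "null"}

#: CDR3 amino-acid markers that flag a non-functional rearrangement.
NONFUNCTIONAL_MARKERS = ("*", "_")

_ALLELE_RE = re.compile(r"\*[0-9]+$")
_NT_RE = re.compile(r"^[ACGT]+$")

#: Canonical internal column order of a clonotype frame.
COLUMNS = (
    "count",
    "frequency",
    "cdr3_nt",
    "cdr3_aa",
    "v_segment",
    "d_segment",
    "j_segment",
)

#: Identity key of a clonotype (the collapse rule).
CLONOTYPE_KEY = ("v_segment", "d_segment", "j_segment", "cdr3_nt")

DIALECTS: dict[str, dict[str, str]] = {
    "vdjtools": {
        "count": "count",
        "freq": "frequency",
        "cdr3nt": "cdr3_nt",
        "cdr3aa": "cdr3_aa",
        "v": "v_segment",
        "d": "d_segment",
        "j": "j_segment",
    },
    "mixcr": {
        "cloneCount": "count",
        "cloneFraction": "frequency",
        "nSeqCDR3": "cdr3_nt",
        "aaSeqCDR3": "cdr3_aa",
        "allVHitsWithScore": "v_segment",
        "allDHitsWithScore": "d_segment",
        "allJHitsWithScore": "j_segment",
    },
}


class ClonotypeTableError(ValueError):
    """Malformed clonotype table (missing column, bad row, ...)."""


class EmptyInputError(ClonotypeTableError):
    """A table or repertoire with no data where data is required."""


class DataIntegrityError(ValueError):
    """Inconsistent data, e.g. one CDR3 nucleotide sequence with two
    different amino-acid translations inside a merge group."""


# ---------------------------------------------------------------------------
# sequence utilities
# ---------------------------------------------------------------------------

def translate_cdr3(cdr3_nt: str) -> str:
    """Translate a CDR3 nucleotide sequence codon-wise.

    Stop codons are rendered as ``*``; a trailing partial codon (length not
    a multiple of 3) is rendered as ``_``, matching the frameshift marker
    convention of MIXCR-style exports.

    Raises
    ------
    ValueError
        if the input contains characters other than A/C/G/T.
    """
    if not isinstance(cdr3_nt, str) or not _NT_RE.match(cdr3_nt):
        raise ValueError(f"invalid CDR3 nucleotide sequence: {cdr3_nt!r}")
    n_full = len(cdr3_nt) - len(cdr3_nt) % 3
    aa = str(Seq(cdr3_nt[:n_full]).translate())
    if n_full != len(cdr3_nt):
        aa += "_"
    return aa


def normalize_segment_name(name: object) -> str:
    """Normalise an IMGT segment name to gene level.

    Strips surrounding whitespace and any allele suffix (``*01``); missing
    value tokens (``.``, empty, ``NA``) map to :data:`MISSING_SEGMENT`, so
    ``TRBV20-1*01`` and ``TRBV20-1`` compare equal at clonotype level.
    """
    if name is None or (isinstance(name, float) and pd.isna(name)):
        return MISSING_SEGMENT
    text = str(name).strip()
    if text.lower() in _MISSING_TOKENS:
        return MISSING_SEGMENT
    return _ALLELE_RE.sub("", text)


def _clean_mixcr_hit(value: object) -> str:
    """Reduce a MIXCR ``allXHitsWithScore`` field to its best gene name."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return MISSING_SEGMENT
    best = str(value).split(",")[0].split("(")[0]
    return normalize_segment_name(best)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ClonotypeRecord:
    """One clonotype-table row (not necessarily collapsed yet)."""

    cdr3_nt: str
    cdr3_aa: str
    v_segment: str
    d_segment: str
    j_segment: str
    count: int
    frequency: float = 0.0

    def key(self) -> tuple[str, str, str, str]:
        """The clonotype identity key (V, D, J, CDR3nt)."""
        return (self.v_segment, self.d_segment, self.j_segment, self.cdr3_nt)

    def is_functional(self, markers: Sequence[str] = NONFUNCTIONAL_MARKERS) -> bool:
        return not any(m in self.cdr3_aa for m in markers)


@dataclasses.dataclass
class Repertoire:
    """One sample's clonotypes plus its metadata.

    ``clonotypes`` is a DataFrame with columns :data:`COLUMNS`; ``diversity``
    is the number of unique clonotypes and ``total_count`` the number of
    UMI-derived molecules, mirroring the usual "diversity" vs "counts"
    bookkeeping of bulk TCR sequencing.
    """

    clonotypes: pd.DataFrame
    donor_id: str | None = None
    subset: str | None = None       # CD4 or CD8
    chain: str | None = None        # TRA or TRB
    condition: str | None = None    # case (antigen-specific) or control (random)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.clonotypes.columns]
        if missing:
            raise ClonotypeTableError(f"clonotype frame lacks columns {missing}")
        self.clonotypes = self.clonotypes.loc[:, list(COLUMNS)].reset_index(drop=True)

    @property
    def diversity(self) -> int:
        return len(self.clonotypes)

    @property
    def total_count(self) -> int:
        return int(self.clonotypes["count"].sum())

    @property
    def sample_key(self) -> tuple:
        return (self.donor_id, self.subset, self.chain, self.condition)

    def records(self) -> Iterator[ClonotypeRecord]:
        for row in self.clonotypes.itertuples(index=False):
            yield ClonotypeRecord(
                cdr3_nt=row.cdr3_nt,
                cdr3_aa=row.cdr3_aa,
                v_segment=row.v_segment,
                d_segment=row.d_segment,
                j_segment=row.j_segment,
                count=int(row.count),
                frequency=float(row.frequency),
            )

    def with_metadata(self, **meta: str | None) -> "Repertoire":
        return dataclasses.replace(self, **meta)


def _records_to_frame(records: Iterable[ClonotypeRecord]) -> pd.DataFrame:
    rows = [
        (r.count, r.frequency, r.cdr3_nt, r.cdr3_aa, r.v_segment, r.d_segment, r.j_segment)
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(COLUMNS))


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def read_clonotype_table(
    path: str | Path,
    dialect: str = "vdjtools",
    metadata: Mapping[str, str] | None = None,
) -> Repertoire:
    """Read a clonotype table into a raw (unmerged, unfiltered) repertoire.

    Segment names are normalised to gene level during ingest; rows are kept
    as-is otherwise — collapsing is :func:`merge_clonotypes`' job and
    functional filtering is :func:`filter_functional`'s.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {sorted(DIALECTS)}")
    mapping = DIALECTS[dialect]

    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in mapping if c not in df.columns]
    if missing:
        raise ClonotypeTableError(
            f"{path.name}: missing required column(s) {missing} for dialect {dialect!r}"
        )
    df = df.rename(columns=mapping).loc[:, [mapping[c] for c in mapping]]
    if len(df) == 0:
        raise EmptyInputError(f"{path.name}: table has a header but no data rows")

    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = counts.isna() | (counts != counts.round()) | (counts < 1)
    if bad.any():
        row = int(bad.idxmax()) + 1  # 1-based data row
        raise ClonotypeTableError(
            f"{path.name}: row {row}: count {df['count'].iloc[row - 1]!r} "
            "is not a positive integer"
        )
    df["count"] = counts.astype(int)
    df["frequency"] = pd.to_numeric(df["frequency"], errors="coerce").fillna(0.0)

    if dialect == "mixcr":
        for col in ("v_segment", "d_segment", "j_segment"):
            df[col] = df[col].map(_clean_mixcr_hit)
    else:
        for col in ("v_segment", "d_segment", "j_segment"):
            df[col] = df[col].map(normalize_segment_name)
    df["cdr3_nt"] = df["cdr3_nt"].str.strip().str.upper()
    df["cdr3_aa"] = df["cdr3_aa"].str.strip()

    rep = Repertoire(clonotypes=df, **(dict(metadata) if metadata else {}))
    log.info("read %d clonotype rows from %s", rep.diversity, path.name)
    return rep


def write_clonotype_table(
    repertoire: Repertoire,
    path: str | Path,
    dialect: str = "vdjtools",
    provenance: Sequence[str] = (),
) -> None:
    """Write a repertoire as a tab-separated clonotype table.

    ``provenance`` lines are prepended as ``#``-comment header lines so a
    re-read (``comment='#'``) round-trips.
    """
    if dialect != "vdjtools":
        raise ValueError("only the vdjtools dialect is supported for writing")
    mapping = DIALECTS["vdjtools"]
    inverse = {v: k for k, v in mapping.items()}
    out = repertoire.clonotypes.rename(columns=inverse).loc[:, list(mapping)]
    path = Path(path)
    with path.open("w") as fh:
        for line in provenance:
            fh.write(f"# {line}\n")
        out.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_manifest(path: str | Path) -> list[dict]:
    """Read a YAML/JSON sample manifest.

    Each entry must provide ``path``, ``donor_id``, ``subset``, ``chain``
    and ``condition``; relative paths are resolved against the manifest's
    directory.
    """
    path = Path(path)
    with path.open() as fh:
        entries = yaml.safe_load(fh)
    if not isinstance(entries, list) or not entries:
        raise ClonotypeTableError(f"{path.name}: manifest must be a non-empty list")
    required = {"path", "donor_id", "subset", "chain", "condition"}
    out = []
    for i, entry in enumerate(entries):
        missing = required - set(entry)
        if missing:
            raise ClonotypeTableError(
                f"{path.name}: manifest entry {i} missing keys {sorted(missing)}"
            )
        entry = dict(entry)
        entry["path"] = str((path.parent / entry["path"]).resolve())
        out.append(entry)
    return out


def load_cohort(
    manifest_path: str | Path, dialect: str = "vdjtools"
) -> list[Repertoire]:
    """Read every sample named in a manifest (raw rows, not yet collapsed)."""
    reps = []
    for entry in read_manifest(manifest_path):
        meta = {k: entry[k] for k in ("donor_id", "subset", "chain", "condition")}
        reps.append(read_clonotype_table(entry["path"], dialect=dialect, metadata=meta))
    return reps


# ---------------------------------------------------------------------------
# collapsing and filtering
# ---------------------------------------------------------------------------

def merge_clonotypes(
    records: Iterable[ClonotypeRecord] | pd.DataFrame | Repertoire,
    **metadata: str | None,
) -> Repertoire:
    """Collapse rows into clonotypes by identical (V, D, J, CDR3nt).

    Member counts are summed, frequencies recomputed as count / total
    count, and the output ordered descending by count with ties broken
    lexicographically by CDR3nt then V segment, so results are
    byte-reproducible.
    """
    if isinstance(records, Repertoire):
        metadata = {
            "donor_id": records.donor_id,
            "subset": records.subset,
            "chain": records.chain,
            "condition": records.condition,
        } | metadata
        df = records.clonotypes.copy()
    elif isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = _records_to_frame(records)

    if len(df) == 0:
        return Repertoire(clonotypes=pd.DataFrame(columns=list(COLUMNS)), **metadata)

    for col in ("v_segment", "d_segment", "j_segment"):
        df[col] = df[col].map(normalize_segment_name)

    key = list(CLONOTYPE_KEY)
    aa_variants = df.groupby(key, sort=False)["cdr3_aa"].nunique()
    if (aa_variants > 1).any():
        clashing = aa_variants[aa_variants > 1].index[0]
        raise DataIntegrityError(
            f"clonotype {clashing} carries conflicting CDR3 amino-acid sequences"
        )

    merged = (
        df.groupby(key, sort=False, as_index=False)
        .agg(count=("count", "sum"), cdr3_aa=("cdr3_aa", "first"))
    )
    total = merged["count"].sum()
    merged["frequency"] = merged["count"] / total
    merged = merged.sort_values(
        ["count", "cdr3_nt", "v_segment"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)

    rep = Repertoire(clonotypes=merged, **metadata)
    log.info(
        "merged %d rows into %d clonotypes (total count %d)",
        len(df), rep.diversity, total,
    )
    return rep


def filter_functional(
    repertoire: Repertoire,
    markers: Sequence[str] = NONFUNCTIONAL_MARKERS,
) -> Repertoire:
    """Drop non-functional clonotypes and renormalise frequencies.

    A clonotype is non-functional if its CDR3 amino-acid sequence carries a
    stop (``*``) or frameshift (``_``) marker.  Surviving frequencies sum to
    one; if everything is removed an empty repertoire is returned with a
    warning.
    """
    df = repertoire.clonotypes
    bad = pd.Series(False, index=df.index)
    for marker in markers:
        bad |= df["cdr3_aa"].str.contains(marker, regex=False)
    kept = df.loc[~bad].copy()
    removed = int(bad.sum())
    if removed:
        log.info(
            "removed %d/%d non-functional clonotypes from %s",
            removed, len(df), repertoire.sample_key,
        )
    if len(kept) == 0:
        if removed:
            log.warning("all clonotypes non-functional in %s", repertoire.sample_key)
        return dataclasses.replace(repertoire, clonotypes=kept)
    kept["frequency"] = kept["count"] / kept["count"].sum()
    return dataclasses.replace(repertoire, clonotypes=kept.reset_index(drop=True))
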