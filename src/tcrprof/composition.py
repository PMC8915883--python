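"""Repertoire descriptors: CDR3 composition, positional profiles, segment usage.

The central metric is a *containment occurrence*: the percentage of
clonotype weight whose full CDR3 amino-acid sequence — conserved C and F
anchors included — contains at least one copy of a residue.  Values for
different residues therefore do not sum to 100.  Weight is either one per
unique clonotype ("diversity", the default, appropriate when clonal
expansions are uninformative) or the clonotype's molecule count ("counts").

Positional profiles report the same quantity per 1-based CDR3 position
counted from the N-terminal conserved C.  By default the denominator is the
whole repertoire, so clonotypes shorter than the queried position count as
non-occurrence and profiles remain comparable across repertoires with
different length distributions; ``conditional=True`` restricts the
denominator to clonotypes long enough to have that position.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .io import EmptyInputError, Repertoire, normalize_segment_name

log = logging.getLogger(__name__)

#: The 20 standard residues, alphabetical single-letter code.
AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Reserved bin for non-standard letters that survive filtering.
OTHER = "other"

Weighting = Literal["diversity", "counts"]


def _weights(repertoire: Repertoire, weighting: Weighting) -> np.ndarray:
    if weighting == "diversity":
        return np.ones(repertoire.diversity)
    if weighting == "counts":
        return repertoire.clonotypes["count"].to_numpy(float)
    raise ValueError(f"weighting must be 'diversity' or 'counts', got {weighting!r}")


def _require_nonempty(repertoire: Repertoire) -> None:
    if repertoire.diversity == 0:
        raise EmptyInputError("descriptor requested for an empty repertoire")


@dataclasses.dataclass
class CompositionProfile:
    sample_key: tuple
    weighting: Weighting
    occurrence: dict[str, float]  # residue -> percentage in [0, 100]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": list(self.occurrence), "value": list(self.occurrence.values())}
        )


@dataclasses.dataclass
class PositionalProfile:
    sample_key: tuple
    weighting: Weighting
    occurrence: dict[tuple[int, str], float]  # (position, residue) -> percentage
    conditional: bool = False

    def at(self, position: int, residue: str) -> float:
        return self.occurrence.get((position, residue), 0.0)

    def to_frame(self) -> pd.DataFrame:
        rows = [(p, aa, v) for (p, aa), v in self.occurrence.items()]
        return pd.DataFrame(rows, columns=["position", "residue", "value"])


@dataclasses.dataclass
class SegmentUsageProfile:
    sample_key: tuple
    weighting: Weighting
    segment_class: Literal["V", "J"]
    usage: dict[str, float]  # segment -> percentage; sums to 100

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": list(self.usage), "value": list(self.usage.values())}
        )


def aa_occurrence(
    repertoire: Repertoire, weighting: Weighting = "diversity"
) -> CompositionProfile:
    """Percentage of clonotype weight containing each residue at least once.

    Anchors are part of the sequence, so C and F sit at (or near) 100 in
    anchor-conserved repertoires.  Non-standard letters are tallied under
    the reserved ``other`` bin and logged, never silently dropped.
    """
    _require_nonempty(repertoire)
    w = _weights(repertoire, weighting)
    total = w.sum()
    seqs = repertoire.clonotypes["cdr3_aa"]
    occurrence = {}
    for aa in AMINO_ACIDS:
        contains = seqs.str.contains(aa, regex=False).to_numpy()
        occurrence[aa] = 100.0 * w[contains].sum() / total
    stray = seqs.str.contains(f"[^{''.join(AMINO_ACIDS)}]", regex=True).to_numpy()
    if stray.any():
        occurrence[OTHER] = 100.0 * w[stray].sum() / total
        log.warning(
            "%s: %d clonotypes carry non-standard CDR3 letters (reported as 'other')",
            repertoire.sample_key, int(stray.sum()),
        )
    return CompositionProfile(repertoire.sample_key, weighting, occurrence)


def percent_change(case_mean: float, control_mean: float) -> float | None:
    """Relative change of a case mean against a control mean, in percent.

    Returns ``None`` (an explicit undefined flag) when the control mean is
    zero but the case mean is not; 0/0 is reported as 0.
    """
    if case_mean < 0 or control_mean < 0:
        raise ValueError("percent_change is defined for non-negative percentages")
    if control_mean == 0:
        return 0.0 if case_mean == 0 else None
    return 100.0 * (case_mean - control_mean) / control_mean


def positional_occurrence(
    repertoire: Repertoire,
    weighting: Weighting = "diversity",
    max_position: int = 15,
    conditional: bool = False,
) -> PositionalProfile:
    """Residue occurrence per CDR3 position (1 = the conserved C).

    ``occurrence(p, X)`` is the weight percentage of clonotypes whose CDR3
    has length >= p with residue X at position p; with the default
    unconditional denominator the sum over residues at position p equals
    the weight percentage of clonotypes of length >= p.
    """
    if max_position < 1:
        raise ValueError("max_position must be >= 1")
    _require_nonempty(repertoire)
    w = _weights(repertoire, weighting)
    total = w.sum()
    seqs = repertoire.clonotypes["cdr3_aa"]
    lengths = seqs.str.len().to_numpy()
    occurrence: dict[tuple[int, str], float] = {}
    for p in range(1, max_position + 1):
        long_enough = lengths >= p
        denom = w[long_enough].sum() if conditional else total
        if denom == 0:
            for aa in AMINO_ACIDS:
                occurrence[(p, aa)] = 0.0
            continue
        chars = seqs.str[p - 1]
        for aa in AMINO_ACIDS:
            hit = (chars == aa).to_numpy() & long_enough
            occurrence[(p, aa)] = 100.0 * w[hit].sum() / denom
    return PositionalProfile(repertoire.sample_key, weighting, occurrence, conditional)


def segment_usage(
    repertoire: Repertoire,
    segment_class: Literal["V", "J"] = "V",
    weighting: Weighting = "diversity",
) -> SegmentUsageProfile:
    """Gene-level segment usage percentages (they sum to 100)."""
    if segment_class not in ("V", "J"):
        raise ValueError("segment_class must be 'V' or 'J'")
    _require_nonempty(repertoire)
    w = _weights(repertoire, weighting)
    col = "v_segment" if segment_class == "V" else "j_segment"
    names = repertoire.clonotypes[col].map(normalize_segment_name)
    totals = pd.Series(w).groupby(names.to_numpy()).sum()
    usage = {seg: 100.0 * val / w.sum() for seg, val in sorted(totals.items())}
    return SegmentUsageProfile(repertoire.sample_key, weighting, segment_class, usage)


def cdr3_length_distribution(
    repertoire: Repertoire, weighting: Weighting = "diversity"
) -> dict[int, float]:
    """Weight percentage per CDR3 amino-acid length (sums to 100)."""
    _require_nonempty(repertoire)
    w = _weights(repertoire, weighting)
    lengths = repertoire.clonotypes["cdr3_aa"].str.len()
    totals = pd.Series(w).groupby(lengths.to_numpy()).sum()
    return {int(length): 100.0 * val / w.sum() for length, val in sorted(totals.items())}
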