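"""Shared fixtures: tiny hand-built repertoires and randomised record pools."""

from __future__ import annotations

import numpy as np
import pytest

from tcrprof.io import ClonotypeRecord, Repertoire, merge_clonotypes
from tcrprof.simulate import AA_TO_CODONS, back_translate


def nt_for_aa(seq: str) -> str:
    """Consistent nucleotide sequence for an aa CDR3, markers included."""
    nt = ""
    for ch in seq:
        if ch == "*":
            nt += "TAA"
        elif ch == "_":
            nt += "A"  # trailing partial codon
        else:
            nt += AA_TO_CODONS[ch][0]
    return nt


def records_from_aa(seqs, counts=None, v=None, d=None, j=None):
    """Build consistent records from amino-acid CDR3s (nt by back-translation)."""
    n = len(seqs)
    counts = counts or [1] * n
    v = v or ["TRBV1"] * n
    d = d or ["TRBD1"] * n
    j = j or ["TRBJ1"] * n
    total = sum(counts)
    return [
        ClonotypeRecord(
            cdr3_nt=nt_for_aa(s),
            cdr3_aa=s,
            v_segment=vi,
            d_segment=di,
            j_segment=ji,
            count=c,
            frequency=c / total,
        )
        for s, c, vi, di, ji in zip(seqs, counts, v, d, j)
    ]


def repertoire_from_aa(seqs, counts=None, **meta) -> Repertoire:
    rep = merge_clonotypes(records_from_aa(seqs, counts), **meta)
    return rep


@pytest.fixture
def make_repertoire():
    return repertoire_from_aa


def random_records(rng: np.random.Generator, n: int) -> list[ClonotypeRecord]:
    """Random records over small alphabets so identity-key collisions occur."""
    nts = ["TGTGCC", "TGTGCA", "TGCGCC", "TGTTGG", "TGTAAA", "TGTTTC"]
    vs = ["TRBV1", "TRBV2", "TRBV20-1"]
    ds = [".", "TRBD1"]
    js = ["TRBJ1", "TRBJ2"]
    out = []
    for _ in range(n):
        nt = nts[rng.integers(len(nts))]
        out.append(
            ClonotypeRecord(
                cdr3_nt=nt,
                cdr3_aa={
                    "TGTGCC": "CA", "TGTGCA": "CA", "TGCGCC": "CA",
                    "TGTTGG": "CW", "TGTAAA": "CK", "TGTTTC": "CF",
                }[nt],
                v_segment=vs[rng.integers(len(vs))],
                d_segment=ds[rng.integers(len(ds))],
                j_segment=js[rng.integers(len(js))],
                count=int(rng.integers(1, 20)),
            )
        )
    return out


def random_repertoire(rng: np.random.Generator, max_clonotypes: int = 50) -> Repertoire:
    """A random functional repertoire of <= max_clonotypes unique clonotypes."""
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    n = int(rng.integers(1, max_clonotypes + 1))
    seen = set()
    records = []
    while len(records) < n:
        length = int(rng.integers(3, 12))
        aa = "C" + "".join(rng.choice(alphabet, length - 2)) + "F"
        v = f"TRBV{rng.integers(1, 6)}"
        j = f"TRBJ{rng.integers(1, 4)}"
        key = (aa, v, j)
        if key in seen:
            continue
        seen.add(key)
        records.append(
            ClonotypeRecord(
                cdr3_nt=back_translate(aa),
                cdr3_aa=aa,
                v_segment=v,
                d_segment="TRBD1",
                j_segment=j,
                count=int(rng.integers(1, 30)),
            )
        )
    return merge_clonotypes(records, donor_id="rand", subset="CD4",
                            chain="TRB", condition="case")
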