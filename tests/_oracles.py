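"""Independent brute-force oracles: literal loops, no pandas vectorisation.

These deliberately re-derive every descriptor and the merge rule from the
definitions, so they share no code path with the implementation.
"""

from __future__ import annotations

import itertools

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def brute_merge(records):
    """Group records by exhaustive pairwise key comparison; sum counts."""
    records = list(records)
    groups: list[list] = []
    for rec in records:
        placed = False
        for group in groups:
            head = group[0]
            if (
                head.v_segment == rec.v_segment
                and head.d_segment == rec.d_segment
                and head.j_segment == rec.j_segment
                and head.cdr3_nt == rec.cdr3_nt
            ):
                group.append(rec)
                placed = True
                break
        if not placed:
            groups.append([rec])
    total = sum(r.count for r in records)
    out = []
    for group in groups:
        count = sum(r.count for r in group)
        out.append(
            {
                "cdr3_nt": group[0].cdr3_nt,
                "cdr3_aa": group[0].cdr3_aa,
                "v_segment": group[0].v_segment,
                "d_segment": group[0].d_segment,
                "j_segment": group[0].j_segment,
                "count": count,
                "frequency": count / total,
            }
        )
    out.sort(key=lambda r: (-r["count"], r["cdr3_nt"], r["v_segment"]))
    return out


def brute_filter(rows):
    """rows: dicts with cdr3_aa/count; keep functional, renormalise."""
    kept = [r for r in rows if "*" not in r["cdr3_aa"] and "_" not in r["cdr3_aa"]]
    total = sum(r["count"] for r in kept)
    out = []
    for r in kept:
        r = dict(r)
        r["frequency"] = r["count"] / total if total else 0.0
        out.append(r)
    return out


def _weights(rows, weighting):
    return [1.0 if weighting == "diversity" else float(r["count"]) for r in rows]


def brute_aa_occurrence(rows, weighting="diversity"):
    w = _weights(rows, weighting)
    total = sum(w)
    occ = {}
    for aa in AA20:
        hit = 0.0
        for r, wi in zip(rows, w):
            if aa in r["cdr3_aa"]:
                hit += wi
        occ[aa] = 100.0 * hit / total
    return occ


def brute_positional(rows, weighting="diversity", max_position=15, conditional=False):
    w = _weights(rows, weighting)
    total = sum(w)
    occ = {}
    for p in range(1, max_position + 1):
        denom = (
            sum(wi for r, wi in zip(rows, w) if len(r["cdr3_aa"]) >= p)
            if conditional
            else total
        )
        for aa in AA20:
            hit = 0.0
            for r, wi in zip(rows, w):
                s = r["cdr3_aa"]
                if len(s) >= p and s[p - 1] == aa:
                    hit += wi
            occ[(p, aa)] = 100.0 * hit / denom if denom else 0.0
    return occ


def brute_segment_usage(rows, segment_class="V", weighting="diversity"):
    key = "v_segment" if segment_class == "V" else "j_segment"
    w = _weights(rows, weighting)
    total = sum(w)
    usage: dict[str, float] = {}
    for r, wi in zip(rows, w):
        usage[r[key]] = usage.get(r[key], 0.0) + wi
    return {seg: 100.0 * v / total for seg, v in usage.items()}


def brute_length_distribution(rows, weighting="diversity"):
    w = _weights(rows, weighting)
    total = sum(w)
    dist: dict[int, float] = {}
    for r, wi in zip(rows, w):
        length = len(r["cdr3_aa"])
        dist[length] = dist.get(length, 0.0) + wi
    return {k: 100.0 * v / total for k, v in dist.items()}


def brute_two_way_anova_ss(values):
    """Classical sums of squares on a balanced layout.

    ``values[(a_level, b_level)]`` is the list of replicates in that cell;
    every cell must hold the same number of replicates.
    """
    a_levels = sorted({a for a, _ in values})
    b_levels = sorted({b for _, b in values})
    r = len(next(iter(values.values())))
    assert all(len(v) == r for v in values.values()), "balanced layouts only"
    flat = [x for cell in values.values() for x in cell]
    grand = sum(flat) / len(flat)

    def mean(xs):
        return sum(xs) / len(xs)

    a_means = {a: mean([x for (ai, _), cell in values.items() if ai == a for x in cell])
               for a in a_levels}
    b_means = {b: mean([x for (_, bi), cell in values.items() if bi == b for x in cell])
               for b in b_levels}
    cell_means = {k: mean(v) for k, v in values.items()}

    n_a, n_b = len(a_levels), len(b_levels)
    ss_a = r * n_b * sum((a_means[a] - grand) ** 2 for a in a_levels)
    ss_b = r * n_a * sum((b_means[b] - grand) ** 2 for b in b_levels)
    ss_ab = r * sum(
        (cell_means[(a, b)] - a_means[a] - b_means[b] + grand) ** 2
        for a, b in itertools.product(a_levels, b_levels)
    )
    ss_res = sum(
        (x - cell_means[k]) ** 2 for k, cell in values.items() for x in cell
    )
    ss_tot = sum((x - grand) ** 2 for x in flat)
    return {
        "A": ss_a, "B": ss_b, "AB": ss_ab,
        "residual": ss_res, "total": ss_tot,
        "df": {"A": n_a - 1, "B": n_b - 1, "AB": (n_a - 1) * (n_b - 1),
               "residual": n_a * n_b * (r - 1)},
    }


def rows_from_repertoire(rep):
    """Repertoire -> list of plain dicts for the oracles above."""
    return [
        {
            "cdr3_nt": rec.cdr3_nt,
            "cdr3_aa": rec.cdr3_aa,
            "v_segment": rec.v_segment,
            "d_segment": rec.d_segment,
            "j_segment": rec.j_segment,
            "count": rec.count,
            "frequency": rec.frequency,
        }
        for rec in rep.records()
    ]
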