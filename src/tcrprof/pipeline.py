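"""End-to-end orchestration: simulate cohorts, run the comparison pipeline.

``run_compare`` automates the full analysis chain on a sample manifest:
read -> collapse to clonotypes -> drop non-functional -> per-sample
descriptor tables -> per-stratum case/control comparison reports.  Outputs
are plain TSV with a provenance comment header (tool version, settings
digest, seed); identical inputs and settings yield byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .composition import (
    aa_occurrence,
    cdr3_length_distribution,
    positional_occurrence,
    segment_usage,
)
from .io import (
    Repertoire,
    filter_functional,
    merge_clonotypes,
    read_clonotype_table,
    read_manifest,
)
from .simulate import SimulationConfig, simulate_cohort, write_cohort
from .stats import (
    InsufficientReplicationError,
    compare_composition,
    comparison_to_frame,
)

log = logging.getLogger(__name__)

DESCRIPTORS = ("aa_occurrence", "positional", "segment_usage")


@dataclasses.dataclass
class PipelineConfig:
    """Settings for one compare run (all recorded in output provenance)."""

    manifest: str
    outdir: str
    dialect: str = "vdjtools"
    weighting: str = "diversity"
    descriptors: tuple[str, ...] = DESCRIPTORS
    positional_aa: str = "W"
    max_position: int = 15
    conditional_positional: bool = False
    welch: bool = False
    min_clonotypes: int = 50
    alpha: float = 0.05
    seed: int | None = None

    def digest(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("manifest")
        payload.pop("outdir")
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _provenance(config: PipelineConfig) -> list[str]:
    return [
        f"tcrprof {__version__}",
        f"settings {config.digest()}",
        f"seed {config.seed if config.seed is not None else 'n/a'}",
    ]


def _write_tsv(df: pd.DataFrame, path: Path, provenance: Sequence[str]) -> None:
    with path.open("w") as fh:
        for line in provenance:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def _sample_name(rep: Repertoire) -> str:
    return f"{rep.donor_id}_{rep.subset}_{rep.chain}_{rep.condition}"


def run_simulate(config: SimulationConfig, outdir: str | Path) -> Path:
    """Generate a cohort and write its tables + manifest.

    Logs the realized occurrence of every requested enrichment target on
    the case arm so simulations are auditable.
    """
    cohort = simulate_cohort(config)
    provenance = [f"tcrprof {__version__}", f"seed {config.seed}"]
    manifest_path = write_cohort(cohort, outdir, provenance=provenance)

    for spec in config.enrichments:
        realized = {}
        for rep in cohort:
            functional = filter_functional(rep)
            if spec.mode == "positional":
                val = positional_occurrence(
                    functional, max_position=spec.position
                ).at(spec.position, spec.target)
            elif spec.mode == "containment":
                val = aa_occurrence(functional).occurrence[spec.target]
            else:
                klass = "V" if spec.target.find("V") >= 0 else "J"
                val = segment_usage(functional, klass).usage.get(spec.target, 0.0)
            realized.setdefault(rep.condition, []).append(val)
        means = {arm: sum(v) / len(v) for arm, v in realized.items()}
        log.info(
            "enrichment %s/%s requested +%.1f points: realized case %.2f%% "
            "vs control %.2f%%",
            spec.mode, spec.target, spec.effect,
            means.get("case", float("nan")), means.get("control", float("nan")),
        )
    return manifest_path


def run_compare(config: PipelineConfig) -> dict[str, list[Path]]:
    """Run the full comparison pipeline; returns written files by category.

    The manifest is validated (every referenced file must exist) before any
    computation, so failures leave no partial outputs.
    """
    entries = read_manifest(config.manifest)
    missing = [e["path"] for e in entries if not Path(e["path"]).is_file()]
    if missing:
        raise FileNotFoundError(
            f"manifest references missing file(s): {missing}"
        )
    for descriptor in config.descriptors:
        if descriptor not in DESCRIPTORS:
            raise ValueError(f"unknown descriptor {descriptor!r}")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    provenance = _provenance(config)

    cohort: list[Repertoire] = []
    checksums: dict[str, str] = {}
    for entry in entries:
        meta = {k: entry[k] for k in ("donor_id", "subset", "chain", "condition")}
        raw = read_clonotype_table(entry["path"], config.dialect, metadata=meta)
        rep = filter_functional(merge_clonotypes(raw))
        cohort.append(rep)
        checksums[Path(entry["path"]).name] = hashlib.sha256(
            Path(entry["path"]).read_bytes()
        ).hexdigest()

    written: dict[str, list[Path]] = {"descriptors": [], "comparisons": [], "log": []}

    for rep in cohort:
        frames = []
        occ = aa_occurrence(rep, config.weighting).to_frame()
        occ.insert(0, "descriptor", "aa_occurrence")
        frames.append(occ)
        lengths = cdr3_length_distribution(rep, config.weighting)
        frames.append(
            pd.DataFrame(
                {
                    "descriptor": "cdr3_length",
                    "feature": [str(k) for k in lengths],
                    "value": list(lengths.values()),
                }
            )
        )
        for klass in ("V", "J"):
            seg = segment_usage(rep, klass, config.weighting).to_frame()
            seg.insert(0, "descriptor", f"segment_usage_{klass}")
            frames.append(seg)
        pos = positional_occurrence(
            rep, config.weighting, config.max_position, config.conditional_positional
        )
        posf = pos.to_frame()
        posf = posf[posf["residue"] == config.positional_aa]
        frames.append(
            pd.DataFrame(
                {
                    "descriptor": "positional",
                    "feature": [
                        f"{r.residue}{r.position}" for r in posf.itertuples()
                    ],
                    "value": posf["value"].to_list(),
                }
            )
        )
        path = outdir / f"{_sample_name(rep)}_descriptors.tsv"
        _write_tsv(pd.concat(frames, ignore_index=True), path, provenance)
        written["descriptors"].append(path)

    strata = sorted({(r.subset, r.chain) for r in cohort})
    for subset, chain in strata:
        members = [r for r in cohort if (r.subset, r.chain) == (subset, chain)]
        for descriptor in config.descriptors:
            try:
                comparisons = compare_composition(
                    members,
                    descriptor,
                    config.weighting,
                    positional_aa=config.positional_aa,
                    max_position=config.max_position,
                    conditional_positional=config.conditional_positional,
                    equal_var=not config.welch,
                    min_clonotypes=config.min_clonotypes,
                )
            except InsufficientReplicationError as exc:
                log.warning(
                    "skipping %s/%s %s: %s", subset, chain, descriptor, exc
                )
                continue
            path = outdir / f"comparison_{subset}_{chain}_{descriptor}.tsv"
            _write_tsv(comparison_to_frame(comparisons), path, provenance)
            written["comparisons"].append(path)

    run_log = outdir / "run_log.txt"
    with run_log.open("w") as fh:
        for line in provenance:
            fh.write(f"# {line}\n")
        fh.write("# settings\n")
        settings = dataclasses.asdict(config)
        # paths are location-dependent and would break byte-reproducibility
        settings.pop("manifest")
        settings.pop("outdir")
        fh.write(json.dumps(settings, sort_keys=True, indent=2))
        fh.write("\n# input checksums (sha256)\n")
        for name, digest in sorted(checksums.items()):
            fh.write(f"{name}\t{digest}\n")
    written["log"].append(run_log)
    return written
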