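"""Config-driven orchestration: alignments → diagnostics → phasing →
networks → hybrid classification → maternal direction → report.

Loci are analyzed independently and joined only at the multilocus
classification step; all randomness flows from the single seed in the
configuration. The consolidated report repeats numbers straight from the
per-stage tables (no recomputation drift).
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, FernHybridError, PipelineStageError
from .hybridcall import (
    AdditivityProfile,
    HybridClassification,
    LocusCall,
    MaternalAssignment,
    additivity_profile,
    classify_individual,
    direction_summary,
    germination_summary,
    locus_combination,
    maternal_assignment,
)
from .mjnetwork import export_network, median_joining
from .phasing import (
    PhasedGenotype,
    em_haplotype_frequencies,
    genotype_from_matrix,
    phase_genotype,
)
from .popseq import (
    CharacterMatrix,
    DiagnosticTable,
    HaplotypePanel,
    collapse_haplotypes,
    detect_indel_events,
    diagnostic_sites,
    merge_panels,
    polymorphism_summary,
    recode_matrix,
)
from .seqio import (
    GerminationRecord,
    Role,
    Taxon,
    read_fasta_alignment,
    read_germination_table,
    write_tables,
)
from .simulate import (
    SimDataset,
    load_sim_config,
    paper_config,
    simulate_dataset,
)

__all__ = ["PipelineConfig", "LocusResult", "PipelineResult",
           "load_pipeline_config", "run_pipeline", "analyze_locus"]


@dataclass(frozen=True)
class LocusInput:
    name: str
    letter: str
    fasta: Path
    sheet: Path


@dataclass(frozen=True)
class PipelineConfig:
    """Exactly one of ``simulate`` (a sim-config path or ``"paper"``) or
    ``inputs`` must be given."""

    seed: int = 0
    output_dir: Path | None = None
    simulate: str | None = None
    inputs: Mapping | None = None
    taxon_map: Mapping[str, str] | None = None
    epsilon: int = 0
    priors: Mapping[str, float] | None = None
    phasing_method: str = "em"  # "em" | "panel"

    def __post_init__(self):
        if (self.simulate is None) == (self.inputs is None):
            raise ConfigError(
                "exactly one of `simulate` or `inputs` must be configured"
            )
        if self.phasing_method not in ("em", "panel"):
            raise ConfigError(
                f"unknown phasing_method {self.phasing_method!r}"
            )


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    inputs = raw.get("inputs")
    if inputs:
        base = path.parent
        inputs = {
            "loci": [
                {
                    "name": d["name"],
                    "letter": d.get("letter", d["name"][0].upper()),
                    "fasta": str(base / d["fasta"]),
                    "sheet": str(base / d["sheet"]),
                }
                for d in inputs.get("loci", [])
            ],
            "chloroplast": (
                {
                    "name": inputs["chloroplast"]["name"],
                    "fasta": str(base / inputs["chloroplast"]["fasta"]),
                    "sheet": str(base / inputs["chloroplast"]["sheet"]),
                }
                if inputs.get("chloroplast")
                else None
            ),
            "germination": (
                str(base / inputs["germination"])
                if inputs.get("germination")
                else None
            ),
        }
    return PipelineConfig(
        seed=int(raw.get("seed", 0)),
        output_dir=Path(raw["output_dir"]) if raw.get("output_dir") else None,
        simulate=raw.get("simulate"),
        inputs=inputs,
        taxon_map=raw.get("taxon_map"),
        epsilon=int(raw.get("epsilon", 0)),
        priors=raw.get("priors"),
        phasing_method=raw.get("phasing_method", "em"),
    )


@dataclass
class LocusResult:
    locus_name: str
    matrix: CharacterMatrix
    panel_a: HaplotypePanel
    panel_b: HaplotypePanel
    dtable: DiagnosticTable
    phased: dict[str, PhasedGenotype]
    additivity: dict[str, AdditivityProfile]
    hybrid_calls: dict[str, LocusCall]
    em_loglik: float | None = None


@dataclass
class PipelineResult:
    loci: dict[str, LocusResult]
    classifications: dict[str, HybridClassification]
    maternal: dict[str, MaternalAssignment]
    direction: dict | None
    germination_rates: pd.DataFrame | None
    germination_tests: pd.DataFrame | None
    report: dict = field(default_factory=dict)


def _stage(stage: str):
    """Decorator-free stage wrapper: re-raise with stage context."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, FernHybridError) and not isinstance(
                exc, PipelineStageError
            ):
                raise PipelineStageError(stage, str(exc)) from exc
            return False

    return _Ctx()


def analyze_locus(
    aln,
    letter: str,
    phasing_method: str = "em",
) -> LocusResult:
    """Run the single-locus chain: indel recoding, panels, diagnostics,
    frequency estimation, phasing, additivity, hybrid combination calls."""
    events = detect_indel_events(aln)
    cm = recode_matrix(aln, events)
    panel_a = collapse_haplotypes(cm, Taxon.SPECIES_A, "a", letter)
    panel_b = collapse_haplotypes(cm, Taxon.SPECIES_B, "s", letter)
    merged = merge_panels(panel_a, panel_b)
    dtable = diagnostic_sites(
        cm,
        cm.sample_ids(role=Role.HAPLOTYPE, taxon=Taxon.SPECIES_A),
        cm.sample_ids(role=Role.HAPLOTYPE, taxon=Taxon.SPECIES_B),
    )
    consensus_ids = cm.sample_ids(role=Role.DIPLOID_CONSENSUS)
    genotypes = [genotype_from_matrix(cm, sid) for sid in consensus_ids]
    freqs, loglik = (None, None)
    if genotypes and phasing_method == "em":
        freqs, loglik = em_haplotype_frequencies(
            genotypes, cm.characters, panel=merged
        )
    phased = {
        g.sample_id: phase_genotype(g, merged, cm.characters, freqs)
        for g in genotypes
    }
    char_index = {ch.id: k for k, ch in enumerate(cm.characters)}
    additivity = {
        g.sample_id: additivity_profile(g, dtable, char_index)
        for g in genotypes
    }
    hybrid_calls = {
        sid: locus_combination(phased[sid], panel_a, panel_b)
        for sid in cm.sample_ids(role=Role.DIPLOID_CONSENSUS, taxon=Taxon.HYBRID)
    }
    return LocusResult(
        locus_name=aln.locus_name,
        matrix=cm,
        panel_a=panel_a,
        panel_b=panel_b,
        dtable=dtable,
        phased=phased,
        additivity=additivity,
        hybrid_calls=hybrid_calls,
        em_loglik=loglik,
    )


def _population_counts(
    result: LocusResult, panel: HaplotypePanel, taxon: Taxon
) -> HaplotypePanel:
    """Re-count a species panel from the phased individuals of that species
    (two haplotypes per diploid), for frequency/summary reporting."""
    counts: dict[tuple[str, str], int] = {}
    names = set(panel.names())
    for sid, pg in result.phased.items():
        rec = result.matrix.record(sid)
        if rec.taxon is not taxon:
            continue
        for name in pg.named_pair:
            if name in names:
                key = (rec.population, name)
                counts[key] = counts.get(key, 0) + 1
    return panel.with_counts(counts) if counts else panel


def _load_inputs(cfg: PipelineConfig):
    loci = []
    for d in cfg.inputs.get("loci", []):
        aln = read_fasta_alignment(
            d["fasta"], d["sheet"], locus_name=d["name"],
            taxon_map=cfg.taxon_map,
        )
        loci.append((d["name"], d.get("letter", d["name"][0].upper()), aln))
    cp = None
    if cfg.inputs.get("chloroplast"):
        d = cfg.inputs["chloroplast"]
        cp = read_fasta_alignment(
            d["fasta"], d["sheet"], locus_name=d["name"],
            taxon_map=cfg.taxon_map,
        )
    germ = None
    if cfg.inputs.get("germination"):
        germ = read_germination_table(cfg.inputs["germination"])
    return loci, cp, germ


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the full analysis and (optionally) write the report bundle."""
    germination: Sequence[GerminationRecord] | None = None
    sim: SimDataset | None = None
    if cfg.simulate is not None:
        with _stage("simulate"):
            simcfg = (
                paper_config(seed=cfg.seed)
                if cfg.simulate == "paper"
                else load_sim_config(cfg.simulate, seed=cfg.seed)
            )
            sim = simulate_dataset(simcfg)
            loci = [
                (spec.name, spec.letter, sim.alignments[spec.name])
                for spec in simcfg.loci
            ]
            cp_aln = sim.alignments[simcfg.chloroplast.name]
            cp_letter = simcfg.chloroplast.letter
            germination = sim.germination
    else:
        with _stage("seqio"):
            in_loci, cp_aln, germination = _load_inputs(cfg)
            loci = in_loci
            cp_letter = "T"

    results: dict[str, LocusResult] = {}
    for name, letter, aln in loci:
        with _stage(f"locus:{name}"):
            results[name] = analyze_locus(
                aln, letter, phasing_method=cfg.phasing_method
            )

    hybrid_ids: list[str] = []
    if results:
        first = next(iter(results.values()))
        hybrid_ids = first.matrix.sample_ids(
            role=Role.DIPLOID_CONSENSUS, taxon=Taxon.HYBRID
        )

    classifications: dict[str, HybridClassification] = {}
    with _stage("classify"):
        for sid in hybrid_ids:
            calls = [
                r.hybrid_calls[sid] for r in results.values()
                if sid in r.hybrid_calls
            ]
            if calls:
                classifications[sid] = classify_individual(calls, cfg.priors)

    maternal: dict[str, MaternalAssignment] = {}
    direction = None
    cp_result: LocusResult | None = None
    if cp_aln is not None:
        with _stage("chloroplast"):
            events = detect_indel_events(cp_aln)
            cm = recode_matrix(cp_aln, events)
            cp_panel_a = collapse_haplotypes(cm, Taxon.SPECIES_A, "a", cp_letter)
            cp_panel_b = collapse_haplotypes(cm, Taxon.SPECIES_B, "s", cp_letter)
            cp_dtable = diagnostic_sites(
                cm,
                cm.sample_ids(role=Role.HAPLOTYPE, taxon=Taxon.SPECIES_A),
                cm.sample_ids(role=Role.HAPLOTYPE, taxon=Taxon.SPECIES_B),
            )
            cp_result = LocusResult(
                locus_name=cp_aln.locus_name,
                matrix=cm,
                panel_a=cp_panel_a,
                panel_b=cp_panel_b,
                dtable=cp_dtable,
                phased={},
                additivity={},
                hybrid_calls={},
            )
            for sid in cm.sample_ids(taxon=Taxon.HYBRID):
                maternal[sid] = maternal_assignment(
                    sid, tuple(cm.states[sid]), cp_panel_a, cp_panel_b
                )
            if maternal:
                direction = direction_summary(list(maternal.values()))

    germ_rates = germ_tests = None
    if germination:
        with _stage("germination"):
            germ_rates, germ_tests = germination_summary(list(germination))

    report = _build_report(
        cfg, results, cp_result, classifications, maternal, direction,
        germ_rates,
    )
    out = PipelineResult(
        loci=results,
        classifications=classifications,
        maternal=maternal,
        direction=direction,
        germination_rates=germ_rates,
        germination_tests=germ_tests,
        report=report,
    )
    if cfg.output_dir is not None:
        with _stage("write"):
            _write_bundle(cfg, out, cp_result, sim)
    return out


def _build_report(cfg, results, cp_result, classifications, maternal,
                  direction, germ_rates) -> dict:
    loci_report = {}
    for name, r in results.items():
        indices = [
            a.additivity_index
            for sid, a in r.additivity.items()
            if r.matrix.record(sid).taxon is Taxon.HYBRID
            and a.additivity_index is not None
        ]
        loci_report[name] = {
            "aligned_length_bp": r.matrix.n_columns,
            "n_characters": r.matrix.n_characters,
            "diagnostic_substitutions": r.dtable.n_substitutions,
            "diagnostic_indels": r.dtable.n_indels,
            "haplotypes_species_A": len(r.panel_a.haplotypes),
            "haplotypes_species_B": len(r.panel_b.haplotypes),
            "mean_hybrid_additivity": (
                sum(indices) / len(indices) if indices else None
            ),
            "em_loglik": r.em_loglik,
        }
    cp_report = None
    if cp_result is not None:
        cp_report = {
            "aligned_length_bp": cp_result.matrix.n_columns,
            "diagnostic_substitutions": cp_result.dtable.n_substitutions,
            "diagnostic_indels": cp_result.dtable.n_indels,
        }
    n_f1 = sum(1 for c in classifications.values() if c.f1_consistent)
    return {
        "version": __version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "epsilon": cfg.epsilon,
        "phasing_method": cfg.phasing_method,
        "loci": loci_report,
        "chloroplast": cp_report,
        "n_hybrids": len(classifications),
        "n_f1_consistent": n_f1,
        "maternal_direction": direction,
        "germination": (
            germ_rates.to_dict(orient="records")
            if germ_rates is not None
            else None
        ),
    }


def _write_bundle(cfg: PipelineConfig, res: PipelineResult,
                  cp_result: LocusResult | None,
                  sim: SimDataset | None) -> None:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}
    for name, r in res.loci.items():
        safe = name.replace("/", "_")
        tables[f"{safe}.diagnostics"] = r.dtable.to_frame()
        tables[f"{safe}.panel"] = pd.concat(
            [r.panel_a.to_frame(), r.panel_b.to_frame()], ignore_index=True
        )
        tables[f"{safe}.phased"] = pd.DataFrame(
            {
                "sample_id": list(r.phased),
                "hap_1": [p.named_pair[0] for p in r.phased.values()],
                "hap_2": [p.named_pair[1] for p in r.phased.values()],
                "method": [p.method for p in r.phased.values()],
                "confidence": [p.confidence for p in r.phased.values()],
            }
        )
        tables[f"{safe}.additivity"] = pd.DataFrame(
            {
                "sample_id": list(r.additivity),
                "n_readable": [a.n_readable for a in r.additivity.values()],
                "n_additive": [a.n_additive for a in r.additivity.values()],
                "additivity_index": [
                    "NA" if a.additivity_index is None else a.additivity_index
                    for a in r.additivity.values()
                ],
            }
        )
        for species, panel in (("A", r.panel_a), ("B", r.panel_b)):
            counted = _population_counts(
                r, panel,
                Taxon.SPECIES_A if species == "A" else Taxon.SPECIES_B,
            )
            tables[f"{safe}.polymorphism_{species}"] = polymorphism_summary(
                counted
            )
            net = median_joining(counted, epsilon=cfg.epsilon)
            export_network(
                net, "edge_tsv", out / f"{safe}.network_{species}.tsv"
            )
    if res.classifications:
        tables["classification"] = pd.DataFrame(
            {
                "sample_id": list(res.classifications),
                "labels": [
                    ";".join(
                        f"{c.locus_name}={c.combination_label}"
                        for c in cl.locus_calls
                    )
                    for cl in res.classifications.values()
                ],
                "patterns": [
                    ",".join(c.cluster_pattern for c in cl.locus_calls)
                    for cl in res.classifications.values()
                ],
                "f1_consistent": [
                    cl.f1_consistent for cl in res.classifications.values()
                ],
                "top_class": [
                    cl.top_class for cl in res.classifications.values()
                ],
                "posterior_F1": [
                    cl.posteriors["F1"] for cl in res.classifications.values()
                ],
            }
        )
    if res.maternal:
        tables["maternal"] = pd.DataFrame(
            {
                "sample_id": list(res.maternal),
                "assigned_species": [
                    m.assigned_species for m in res.maternal.values()
                ],
                "distance_to_A": [
                    m.distance_to_a for m in res.maternal.values()
                ],
                "distance_to_B": [
                    m.distance_to_b for m in res.maternal.values()
                ],
            }
        )
    if res.germination_rates is not None:
        tables["germination_rates"] = res.germination_rates
        tables["germination_tests"] = res.germination_tests
    write_tables(tables, out)
    with open(out / "report.json", "w", newline="\n") as fh:
        json.dump(res.report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "report.txt", "w", newline="\n") as fh:
        fh.write(_format_report(res.report))
    if sim is not None:
        from .simulate import write_dataset

        write_dataset(sim, out / "simulated_input")


def _format_report(rep: dict) -> str:
    lines = [
        f"fernhybrid {rep['version']} (python {rep['python']}), "
        f"seed={rep['seed']}, phasing={rep['phasing_method']}, "
        f"epsilon={rep['epsilon']}",
        "",
    ]
    for name, r in rep["loci"].items():
        add = r["mean_hybrid_additivity"]
        lines.append(
            f"{name}: {r['aligned_length_bp']} bp aligned, "
            f"{r['diagnostic_substitutions']} fixed substitutions + "
            f"{r['diagnostic_indels']} fixed indel event(s); "
            f"{r['haplotypes_species_A']} species-A / "
            f"{r['haplotypes_species_B']} species-B haplotypes; "
            f"mean hybrid additivity "
            f"{'NA' if add is None else format(add, '.3f')}"
        )
    if rep["chloroplast"]:
        c = rep["chloroplast"]
        lines.append(
            f"chloroplast: {c['aligned_length_bp']} bp aligned, "
            f"{c['diagnostic_substitutions']} substitutions + "
            f"{c['diagnostic_indels']} indel event(s) between species"
        )
    lines.append(
        f"hybrids: {rep['n_f1_consistent']}/{rep['n_hybrids']} F1-consistent"
    )
    if rep["maternal_direction"]:
        d = rep["maternal_direction"]
        lines.append(
            f"maternal direction: {d['n_species_B']} species_B vs "
            f"{d['n_species_A']} species_A "
            f"(proportion B = {d['proportion_B_maternal']:.3f}, "
            f"binomial p = {d['binomial_p']:.3g}; test added here, not a "
            "source statistic)"
        )
    if rep["germination"]:
        for g in rep["germination"]:
            lines.append(
                f"germination {g['taxon']}: {g['rate']:.1%} "
                f"({g['germinated']}/{g['total']}, "
                f"Wilson 95% {g['wilson_low']:.3f}-{g['wilson_high']:.3f})"
            )
    return "\n".join(lines) + "\n"
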