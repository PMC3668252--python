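"""Synthetic two-species + hybrid study generator with truth tables.

The generator emulates the structure of a Sanger-era hybrid-diagnosis study:

* two long-diverged species with a handful of fixed interspecific
  differences per nuclear locus (substitutions and whole indel events) and
  star-like within-species variation (private mutations off a core
  haplotype, disjoint from the diagnostic positions);
* diploid individuals drawn in Hardy–Weinberg proportions within each
  population; hybrids of configurable generation classes (F1, F2,
  backcrosses) with free recombination between loci and none within;
* direct-sequencing consensus rows per individual, IUPAC-coded at
  heterozygous sites, with the heterozygous-indel read failure: from the
  first column where exactly one allele is gapped, the trace is unreadable
  and everything downstream becomes N;
* uniparental chloroplast transmission per a configurable maternal rule;
* per-base consensus miscall errors at a configurable rate; binomial spore
  germination counts.

Everything is deterministic given the seed, and the emitted truth tables
(true haplotype pairs, generation class, maternal species, diagnostic
counts) are consistent with the emitted sequences by construction.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .seqio import (
    BASES,
    Role,
    SampleRecord,
    SiteAlignment,
    Taxon,
    GerminationRecord,
    write_fasta_alignment,
    write_sample_sheet,
)

__all__ = [
    "IndelSpec",
    "LocusSpec",
    "SimConfig",
    "SimDataset",
    "load_sim_config",
    "paper_config",
    "build_species_pair",
    "simulate_individuals",
    "simulate_dataset",
    "write_dataset",
]

_SPECIES = (Taxon.SPECIES_A, Taxon.SPECIES_B)
_TAG = {Taxon.SPECIES_A: "a", Taxon.SPECIES_B: "s"}
_HYBRID_CLASSES = ("F1", "F2", "BC_A", "BC_B")


@dataclass(frozen=True)
class IndelSpec:
    length: int
    at: float | None = None  # fractional position along the locus
    position: int | None = None  # explicit start column (overrides `at`)


@dataclass(frozen=True)
class LocusSpec:
    name: str
    letter: str
    length: int
    fixed_substitutions: int
    indels: tuple[IndelSpec, ...] = ()
    haplotypes: Mapping[str, tuple[int, ...]] = field(default_factory=dict)
    frequencies: Mapping[str, Mapping[str, tuple[float, ...]]] = field(
        default_factory=dict
    )

    def pop_freqs(self, species: Taxon, population: str) -> tuple[float, ...]:
        table = self.frequencies.get(species.value, {})
        if population in table:
            return table[population]
        if "default" in table:
            return table["default"]
        k = len(self.haplotypes.get(species.value, (0,)))
        return tuple([1.0] + [0.0] * (k - 1))


@dataclass(frozen=True)
class GerminationSpec:
    rate: float
    spores: int


@dataclass(frozen=True)
class SimConfig:
    loci: tuple[LocusSpec, ...]
    chloroplast: LocusSpec
    populations: Mapping[str, Mapping[str, int]]
    hybrid_populations: Mapping[str, int]
    hybrid_classes: Mapping[str, int]
    maternal_rule: str = "always_B"
    sequencing_error_rate: float = 0.0
    germination: Mapping[str, GerminationSpec] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.maternal_rule not in ("always_A", "always_B", "random"):
            raise ConfigError(f"unknown maternal_rule {self.maternal_rule!r}")
        if sum(self.hybrid_classes.values()) != sum(
            self.hybrid_populations.values()
        ):
            raise ConfigError(
                "hybrid class counts must sum to the hybrid population counts"
            )
        for spec in (*self.loci, self.chloroplast):
            for sp, freq_table in spec.frequencies.items():
                k = len(spec.haplotypes.get(sp, ()))
                for pop, freqs in freq_table.items():
                    if len(freqs) != k:
                        raise ConfigError(
                            f"{spec.name}/{sp}/{pop}: {len(freqs)} "
                            f"frequencies for {k} haplotypes"
                        )
                    if abs(sum(freqs) - 1.0) > 1e-9:
                        raise ConfigError(
                            f"{spec.name}/{sp}/{pop}: frequencies sum to "
                            f"{sum(freqs)}, not 1"
                        )
            needed = (
                spec.fixed_substitutions
                + sum(iv.length for iv in spec.indels)
                + sum(
                    sum(muts)
                    for muts in spec.haplotypes.values()
                )
            )
            if needed > spec.length:
                raise ConfigError(
                    f"{spec.name}: {needed} mutated columns do not fit in "
                    f"{spec.length} bp"
                )


def _locus_from_dict(d: Mapping, default_haps: bool = False) -> LocusSpec:
    indels = tuple(
        IndelSpec(
            length=int(iv["length"]),
            at=iv.get("at"),
            position=iv.get("position"),
        )
        for iv in d.get("indels", [])
    )
    haplotypes = {
        sp: tuple(int(x) for x in muts)
        for sp, muts in d.get("haplotypes", {}).items()
    }
    if not haplotypes and default_haps:
        haplotypes = {t.value: (0,) for t in _SPECIES}
    frequencies = {
        sp: {pop: tuple(float(x) for x in fr) for pop, fr in table.items()}
        for sp, table in d.get("frequencies", {}).items()
    }
    return LocusSpec(
        name=str(d["name"]),
        letter=str(d.get("letter", d["name"][0].upper())),
        length=int(d["length"]),
        fixed_substitutions=int(d["fixed_substitutions"]),
        indels=indels,
        haplotypes=haplotypes,
        frequencies=frequencies,
    )


def _config_from_dict(raw: Mapping, seed: int = 0) -> SimConfig:
    germ = {
        taxon: GerminationSpec(float(g["rate"]), int(g["spores"]))
        for taxon, g in raw.get("germination", {}).items()
    }
    hybrids = raw.get("hybrids", {})
    return SimConfig(
        loci=tuple(_locus_from_dict(d) for d in raw["loci"]),
        chloroplast=_locus_from_dict(raw["chloroplast"], default_haps=True),
        populations={
            sp: dict(pops) for sp, pops in raw["populations"].items()
        },
        hybrid_populations=dict(hybrids.get("populations", {})),
        hybrid_classes={
            c: int(hybrids.get("classes", {}).get(c, 0))
            for c in _HYBRID_CLASSES
        },
        maternal_rule=raw.get("maternal_rule", "always_B"),
        sequencing_error_rate=float(raw.get("sequencing_error_rate", 0.0)),
        germination=germ,
        seed=seed,
    )


def load_sim_config(path: str | Path, seed: int = 0) -> SimConfig:
    with open(path) as fh:
        return _config_from_dict(yaml.safe_load(fh), seed=seed)


def paper_config(seed: int = 0) -> SimConfig:
    """The packaged default configuration emulating the published study."""
    text = (
        importlib.resources.files("fernhybrid.data")
        .joinpath("paper_config.yaml")
        .read_text()
    )
    return _config_from_dict(yaml.safe_load(text), seed=seed)


# ---------------------------------------------------------------------------
# species-pair construction


@dataclass(frozen=True)
class LocusPanels:
    """Per-species named haplotype sequences for one locus (aligned)."""

    spec: LocusSpec
    haplotypes: Mapping[str, tuple[tuple[str, str], ...]]  # species -> (name, seq)
    fixed_positions: tuple[int, ...]
    indel_intervals: tuple[tuple[int, int], ...]

    def names(self, species: Taxon) -> list[str]:
        return [n for n, _ in self.haplotypes[species.value]]

    def seq(self, species: Taxon, index: int) -> str:
        return self.haplotypes[species.value][index][1]


def _place_indels(spec: LocusSpec) -> list[tuple[int, int]]:
    intervals: list[tuple[int, int]] = []
    for iv in spec.indels:
        if iv.position is not None:
            start = iv.position
        elif iv.at is not None:
            start = int(round(iv.at * spec.length))
        else:
            raise ConfigError(f"{spec.name}: indel needs `at` or `position`")
        end = start + iv.length
        if not (0 <= start < end <= spec.length):
            raise ConfigError(
                f"{spec.name}: indel [{start},{end}) outside the locus"
            )
        for s, e in intervals:
            if start < e and s < end:
                raise ConfigError(f"{spec.name}: overlapping indels")
        intervals.append((start, end))
    return sorted(intervals)


def _build_locus(spec: LocusSpec, rng: np.random.Generator) -> LocusPanels:
    intervals = _place_indels(spec)
    in_indel = {c for s, e in intervals for c in range(s, e)}
    free = [c for c in range(spec.length) if c not in in_indel]
    total_private = sum(sum(m) for m in spec.haplotypes.values())
    if spec.fixed_substitutions + total_private > len(free):
        raise ConfigError(
            f"{spec.name}: mutation placement collision — "
            f"{spec.fixed_substitutions + total_private} substitutions for "
            f"{len(free)} free columns"
        )
    picks = rng.choice(len(free), spec.fixed_substitutions + total_private,
                       replace=False)
    cols = [free[i] for i in picks]
    fixed_pos = sorted(cols[: spec.fixed_substitutions])
    private_pool = cols[spec.fixed_substitutions:]

    ancestral = "".join(rng.choice(list(BASES), size=spec.length))

    def mutate(seq: str, pos: int) -> str:
        alt = rng.choice([b for b in BASES if b != seq[pos]])
        return seq[:pos] + alt + seq[pos + 1:]

    core = {Taxon.SPECIES_A: ancestral}
    b = ancestral
    for pos in fixed_pos:
        b = mutate(b, pos)
    for s, e in intervals:
        b = b[:s] + "-" * (e - s) + b[e:]  # species B carries the deletion
    core[Taxon.SPECIES_B] = b

    pool_iter = iter(private_pool)
    haplotypes: dict[str, tuple[tuple[str, str], ...]] = {}
    for species in _SPECIES:
        muts = spec.haplotypes.get(species.value, (0,))
        if muts and muts[0] != 0:
            raise ConfigError(
                f"{spec.name}/{species.value}: first haplotype must be the "
                "core (0 extra mutations)"
            )
        out = []
        for i, k in enumerate(muts):
            seq = core[species]
            for _ in range(k):
                pos = next(pool_iter)
                if seq[pos] == "-":
                    raise ConfigError(
                        f"{spec.name}: private mutation fell into an indel"
                    )
                seq = mutate(seq, pos)
            out.append((f"{_TAG[species]}{spec.letter}{i + 1}", seq))
        haplotypes[species.value] = tuple(out)
    return LocusPanels(
        spec=spec,
        haplotypes=haplotypes,
        fixed_positions=tuple(fixed_pos),
        indel_intervals=tuple(intervals),
    )


def build_species_pair(
    cfg: SimConfig, rng: np.random.Generator
) -> dict[str, LocusPanels]:
    """Ancestral sequence + species cores + within-species haplotypes for
    every locus (nuclear and chloroplast); deterministic given the rng."""
    panels = {}
    for spec in cfg.loci:
        panels[spec.name] = _build_locus(spec, rng)
    panels[cfg.chloroplast.name] = _build_locus(cfg.chloroplast, rng)
    return panels


# ---------------------------------------------------------------------------
# individuals


def consensus_of_sequences(s1: str, s2: str) -> tuple[str, int]:
    """Direct-sequencing consensus of two aligned haplotype sequences.

    Matching characters pass through; two different bases superimpose into
    the IUPAC code; from the first column where exactly one allele is gapped
    (a heterozygous indel) the read fails and the rest is N. Returns the
    consensus and the readable prefix length.
    """
    from .seqio import iupac_union  # local import to avoid cycle at module load

    out: list[str] = []
    prefix = len(s1)
    for c, (a, b) in enumerate(zip(s1, s2)):
        if (a == "-") != (b == "-"):
            prefix = c
            break
        if a == b:
            out.append(a)
        elif a == "N" or b == "N":
            out.append("N")
        else:
            out.append(iupac_union(a, b))
    if prefix < len(s1):
        out = out[:prefix] + ["N"] * (len(s1) - prefix)
    return "".join(out), prefix


@dataclass
class SimDataset:
    config: SimConfig
    alignments: Mapping[str, SiteAlignment]  # locus (incl. chloroplast) -> aln
    truth_individuals: pd.DataFrame
    truth_pairs: pd.DataFrame
    truth_diagnostics: pd.DataFrame
    germination: tuple[GerminationRecord, ...]

    @property
    def nuclear_loci(self) -> list[str]:
        return [spec.name for spec in self.config.loci]

    @property
    def chloroplast_locus(self) -> str:
        return self.config.chloroplast.name


def _draw_hap(
    rng: np.random.Generator,
    panels: LocusPanels,
    species: Taxon,
    population: str,
) -> int:
    freqs = np.asarray(panels.spec.pop_freqs(species, population))
    return int(rng.choice(len(freqs), p=freqs))


def simulate_individuals(
    cfg: SimConfig,
    panels: Mapping[str, LocusPanels],
    rng: np.random.Generator,
) -> SimDataset:
    """Draw parental and hybrid individuals and emit per-locus alignments.

    Each alignment holds the species haplotype panel as haplotype-role
    reference rows (the in-silico analogue of deposited phased sequences)
    plus one diploid-consensus row per individual. The chloroplast alignment
    carries one haplotype-role row per individual (organelles are haploid).
    """
    # roster: (sample_id, taxon, population, class)
    roster: list[tuple[str, Taxon, str, str]] = []
    for species in _SPECIES:
        short = "A" if species is Taxon.SPECIES_A else "B"
        for pop, n in cfg.populations.get(species.value, {}).items():
            for i in range(n):
                roster.append(
                    (f"{short}_{pop}_{i + 1:03d}", species, pop,
                     "pure_A" if species is Taxon.SPECIES_A else "pure_B")
                )
    class_queue = [
        cls for cls in _HYBRID_CLASSES
        for _ in range(cfg.hybrid_classes.get(cls, 0))
    ]
    qi = 0
    for pop, n in cfg.hybrid_populations.items():
        for i in range(n):
            roster.append((f"H_{pop}_{i + 1:03d}", Taxon.HYBRID, pop,
                           class_queue[qi]))
            qi += 1

    maternal: dict[str, Taxon] = {}
    for sid, taxon, pop, cls in roster:
        if taxon is Taxon.HYBRID:
            if cfg.maternal_rule == "always_A":
                maternal[sid] = Taxon.SPECIES_A
            elif cfg.maternal_rule == "always_B":
                maternal[sid] = Taxon.SPECIES_B
            else:
                maternal[sid] = _SPECIES[int(rng.integers(2))]
        else:
            maternal[sid] = taxon

    err = cfg.sequencing_error_rate

    def apply_error(seq: str, prefix: int) -> str:
        if err <= 0.0:
            return seq
        chars = list(seq)
        for c in range(min(prefix, len(chars))):
            if chars[c] in ("-", "N"):
                continue
            if rng.random() < err:
                chars[c] = rng.choice(list(BASES))
        return "".join(chars)

    alignments: dict[str, SiteAlignment] = {}
    pair_rows: list[dict] = []
    for spec in cfg.loci:
        pl = panels[spec.name]
        samples: list[SampleRecord] = []
        matrix: list[str] = []
        for species in _SPECIES:
            for name, seq in pl.haplotypes[species.value]:
                samples.append(
                    SampleRecord(name, species, "panel", Role.HAPLOTYPE)
                )
                matrix.append(seq)

        def gamete(pop: str) -> tuple[str, str]:
            """One meiotic product of an F1: either its A or its B haplotype
            at this locus (free recombination between loci)."""
            ia = _draw_hap(rng, pl, Taxon.SPECIES_A, pop)
            ib = _draw_hap(rng, pl, Taxon.SPECIES_B, pop)
            if rng.integers(2):
                return pl.names(Taxon.SPECIES_B)[ib], pl.seq(Taxon.SPECIES_B, ib)
            return pl.names(Taxon.SPECIES_A)[ia], pl.seq(Taxon.SPECIES_A, ia)

        def parental_draw(species: Taxon, pop: str) -> tuple[str, str]:
            i = _draw_hap(rng, pl, species, pop)
            return pl.names(species)[i], pl.seq(species, i)

        for sid, taxon, pop, cls in roster:
            if cls in ("pure_A", "pure_B"):
                species = Taxon.SPECIES_A if cls == "pure_A" else Taxon.SPECIES_B
                h1 = parental_draw(species, pop)
                h2 = parental_draw(species, pop)
            elif cls == "F1":
                h1 = parental_draw(Taxon.SPECIES_A, pop)
                h2 = parental_draw(Taxon.SPECIES_B, pop)
            elif cls == "F2":
                h1, h2 = gamete(pop), gamete(pop)
            elif cls == "BC_A":
                h1, h2 = gamete(pop), parental_draw(Taxon.SPECIES_A, pop)
            else:  # BC_B
                h1, h2 = gamete(pop), parental_draw(Taxon.SPECIES_B, pop)
            consensus, prefix = consensus_of_sequences(h1[1], h2[1])
            consensus = apply_error(consensus, prefix)
            samples.append(
                SampleRecord(
                    sid,
                    taxon,
                    pop,
                    Role.DIPLOID_CONSENSUS,
                    readable_prefix=None if prefix >= spec.length else prefix,
                )
            )
            matrix.append(consensus)
            pair_rows.append(
                {
                    "sample_id": sid,
                    "locus": spec.name,
                    "hap_1": min(h1[0], h2[0]),
                    "hap_2": max(h1[0], h2[0]),
                }
            )
        alignments[spec.name] = SiteAlignment(
            locus_name=spec.name,
            samples=tuple(samples),
            matrix=tuple(matrix),
        )

    # chloroplast: haploid, maternally transmitted
    cp = panels[cfg.chloroplast.name]
    samples = []
    matrix = []
    for species in _SPECIES:
        for name, seq in cp.haplotypes[species.value]:
            samples.append(SampleRecord(name, species, "panel", Role.HAPLOTYPE))
            matrix.append(seq)
    for sid, taxon, pop, cls in roster:
        mother = maternal[sid]
        i = _draw_hap(rng, cp, mother, pop)
        seq = apply_error(cp.seq(mother, i), cfg.chloroplast.length)
        samples.append(SampleRecord(sid, taxon, pop, Role.HAPLOTYPE))
        matrix.append(seq)
    alignments[cfg.chloroplast.name] = SiteAlignment(
        locus_name=cfg.chloroplast.name,
        samples=tuple(samples),
        matrix=tuple(matrix),
    )

    truth_individuals = pd.DataFrame(
        {
            "sample_id": [sid for sid, *_ in roster],
            "taxon": [t.value for _, t, *_ in roster],
            "population": [p for _, _, p, _ in roster],
            "generation_class": [c for *_, c in roster],
            "maternal_species": [maternal[sid].value for sid, *_ in roster],
        }
    )
    diag_rows = []
    for spec in (*cfg.loci, cfg.chloroplast):
        diag_rows.append(
            {
                "locus": spec.name,
                "n_fixed_substitutions": spec.fixed_substitutions,
                "n_fixed_indels": len(spec.indels),
            }
        )
    germination = tuple(
        GerminationRecord(
            taxon=taxon,
            germinated=int(rng.binomial(g.spores, g.rate)),
            total=g.spores,
        )
        for taxon, g in cfg.germination.items()
    )
    return SimDataset(
        config=cfg,
        alignments=alignments,
        truth_individuals=truth_individuals,
        truth_pairs=pd.DataFrame(pair_rows),
        truth_diagnostics=pd.DataFrame(diag_rows),
        germination=germination,
    )


def simulate_dataset(cfg: SimConfig, seed: int | None = None) -> SimDataset:
    """build_species_pair + simulate_individuals from a single seed."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    panels = build_species_pair(cfg, rng)
    return simulate_individuals(cfg, panels, rng)


def write_dataset(ds: SimDataset, out_dir: str | Path) -> Path:
    """Write FASTA + sample sheet per locus, truth TSVs, germination TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for locus, aln in ds.alignments.items():
        safe = locus.replace("/", "_")
        write_fasta_alignment(aln, out_dir / f"{safe}.fasta")
        write_sample_sheet(aln, out_dir / f"{safe}.samples.tsv")
    truth = out_dir / "truth"
    truth.mkdir(exist_ok=True)
    kw = dict(sep="\t", index=False, lineterminator="\n")
    ds.truth_individuals.to_csv(truth / "individuals.tsv", **kw)
    ds.truth_pairs.to_csv(truth / "haplotype_pairs.tsv", **kw)
    ds.truth_diagnostics.to_csv(truth / "diagnostics.tsv", **kw)
    pd.DataFrame(
        {
            "taxon": [g.taxon for g in ds.germination],
            "germinated": [g.germinated for g in ds.germination],
            "total": [g.total for g in ds.germination],
        }
    ).to_csv(out_dir / "germination.tsv", **kw)
    return out_dir
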