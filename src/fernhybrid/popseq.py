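"""Indel-event recoding, fixed-difference calling, and haplotype panels.

A contiguous run of gap-containing columns that share a single per-sample
presence pattern is one *indel event* and becomes one binary character, so a
5-bp insertion/deletion counts as a single mutational step, matching the way
haplotype networks score indels. Substitution columns outside events remain
one character each.

A character is *diagnostic* (a fixed interspecific difference) when every
non-missing state in species A is one state, every non-missing state in
species B is a different single state. Missing states (N) are ignored but
flagged — the permissive rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import AlignmentError, DataError, InternalError, RoleError
from .seqio import (
    AMBIGUITY_CODES,
    Role,
    SampleRecord,
    SiteAlignment,
    Taxon,
)

__all__ = [
    "IndelEvent",
    "Character",
    "CharacterMatrix",
    "DiagnosticSite",
    "DiagnosticTable",
    "Haplotype",
    "HaplotypePanel",
    "detect_indel_events",
    "recode_matrix",
    "diagnostic_sites",
    "collapse_haplotypes",
    "merge_panels",
    "polymorphism_summary",
]

#: binary states of an indel character
PRESENT, ABSENT = "1", "0"


@dataclass(frozen=True)
class IndelEvent:
    """A maximal gapped column run with one per-sample presence pattern."""

    event_id: str
    start: int
    end: int  # half-open
    presence: Mapping[str, bool]  # sample_id -> has bases in [start, end)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Character:
    id: str
    kind: str  # "substitution" | "indel"
    source_columns: tuple[int, ...]
    flags: tuple[str, ...] = ()

    @property
    def position(self) -> int:
        return self.source_columns[0]


@dataclass(frozen=True)
class CharacterMatrix:
    """Alignment recoded as substitution + binary indel characters."""

    locus_name: str
    characters: tuple[Character, ...]
    samples: tuple[SampleRecord, ...]
    states: Mapping[str, tuple[str, ...]]  # sample_id -> per-character state
    events: tuple[IndelEvent, ...] = ()

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    @property
    def n_columns(self) -> int:
        return max(max(c.source_columns) for c in self.characters) + 1

    def sample_ids(
        self,
        role: Role | None = None,
        taxon: Taxon | None = None,
    ) -> list[str]:
        return [
            s.sample_id
            for s in self.samples
            if (role is None or s.role is role)
            and (taxon is None or s.taxon is taxon)
        ]

    def record(self, sample_id: str) -> SampleRecord:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)


@dataclass(frozen=True)
class DiagnosticSite:
    character_id: str
    kind: str
    allele_a: str
    allele_b: str
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class DiagnosticTable:
    locus_name: str
    rows: tuple[DiagnosticSite, ...]

    @property
    def n_substitutions(self) -> int:
        return sum(1 for r in self.rows if r.kind == "substitution")

    @property
    def n_indels(self) -> int:
        return sum(1 for r in self.rows if r.kind == "indel")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "character_id": [r.character_id for r in self.rows],
                "kind": [r.kind for r in self.rows],
                "allele_A": [r.allele_a for r in self.rows],
                "allele_B": [r.allele_b for r in self.rows],
                "flags": [";".join(r.flags) for r in self.rows],
            }
        )


@dataclass(frozen=True)
class Haplotype:
    name: str
    states: tuple[str, ...]
    species: Taxon


@dataclass(frozen=True)
class HaplotypePanel:
    """Named haplotypes of one locus with per-population counts."""

    locus_name: str
    haplotypes: tuple[Haplotype, ...]
    counts: Mapping[tuple[str, str], int] = field(default_factory=dict)

    def names(self) -> list[str]:
        return [h.name for h in self.haplotypes]

    def get(self, name: str) -> Haplotype:
        for h in self.haplotypes:
            if h.name == name:
                return h
        raise KeyError(name)

    def total_count(self, name: str) -> int:
        return sum(v for (_, n), v in self.counts.items() if n == name)

    def populations(self) -> list[str]:
        return sorted({p for (p, _) in self.counts})

    def with_counts(
        self, counts: Mapping[tuple[str, str], int]
    ) -> "HaplotypePanel":
        return HaplotypePanel(self.locus_name, self.haplotypes, dict(counts))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [h.name for h in self.haplotypes],
                "species": [h.species.value for h in self.haplotypes],
                "total_count": [self.total_count(h.name) for h in self.haplotypes],
                "states": ["".join(h.states) for h in self.haplotypes],
            }
        )


def detect_indel_events(aln: SiteAlignment) -> list[IndelEvent]:
    """Group gapped columns into indel events (haplotype-role rows only)."""
    rows = [
        (rec.sample_id, aln.matrix[i])
        for i, rec in enumerate(aln.samples)
        if rec.role is Role.HAPLOTYPE
    ]
    if not rows:
        raise RoleError(
            f"{aln.locus_name}: no haplotype-role rows to scan for indels"
        )
    events: list[IndelEvent] = []
    cur_start: int | None = None
    cur_pattern: tuple[bool, ...] | None = None

    def _flush(end: int):
        nonlocal cur_start, cur_pattern
        if cur_start is not None:
            events.append(
                IndelEvent(
                    event_id=f"i{cur_start:04d}",
                    start=cur_start,
                    end=end,
                    presence={
                        sid: pres
                        for (sid, _), pres in zip(rows, cur_pattern)
                    },
                )
            )
        cur_start, cur_pattern = None, None

    for c in range(aln.columns):
        col = [seq[c] for _, seq in rows]
        if all(ch == "-" for ch in col):
            raise AlignmentError(
                f"{aln.locus_name}: column {c} is all-gap (uninformative)"
            )
        if any(ch == "-" for ch in col):
            pattern = tuple(ch != "-" for ch in col)
            if cur_pattern == pattern:
                continue  # extend current run
            _flush(c)
            cur_start, cur_pattern = c, pattern
        else:
            _flush(c)
    _flush(aln.columns)
    return events


def _indel_state(segment: str) -> str:
    if all(ch == "-" for ch in segment):
        return ABSENT
    if "N" in segment or "-" in segment:
        return "N"
    return PRESENT


def recode_matrix(
    aln: SiteAlignment, events: Sequence[IndelEvent]
) -> CharacterMatrix:
    """Recode an alignment into substitution + binary indel characters.

    Consensus rows keep IUPAC states at substitution characters; a
    heterozygous indel cannot be represented as a state (the frame-shifted
    trace is unreadable), so everything at or beyond a row's
    ``readable_prefix`` becomes N.
    """
    covered: set[int] = set()
    for ev in events:
        span = set(range(ev.start, ev.end))
        if span & covered:
            raise InternalError(f"{aln.locus_name}: overlapping indel events")
        covered |= span

    characters: list[Character] = []
    for c in range(aln.columns):
        if c not in covered:
            characters.append(
                Character(id=f"s{c:04d}", kind="substitution",
                          source_columns=(c,))
            )
    for ev in events:
        characters.append(
            Character(
                id=ev.event_id,
                kind="indel",
                source_columns=tuple(range(ev.start, ev.end)),
            )
        )
    characters.sort(key=lambda ch: ch.position)

    states: dict[str, tuple[str, ...]] = {}
    for rec, row in zip(aln.samples, aln.matrix):
        vec: list[str] = []
        for ch in characters:
            if ch.kind == "substitution":
                vec.append(row[ch.source_columns[0]])
            else:
                seg = "".join(row[c] for c in ch.source_columns)
                vec.append(_indel_state(seg))
        if rec.readable_prefix is not None:
            rp = rec.readable_prefix
            vec = [
                "N" if any(c >= rp for c in ch.source_columns) else st
                for ch, st in zip(characters, vec)
            ]
        states[rec.sample_id] = tuple(vec)

    # flag characters invariant across haplotype-role rows
    hap_ids = [s.sample_id for s in aln.samples if s.role is Role.HAPLOTYPE]
    flagged: list[Character] = []
    for k, ch in enumerate(characters):
        observed = {states[sid][k] for sid in hap_ids} - {"N"}
        flags = ("invariant",) if len(observed) <= 1 else ()
        flagged.append(
            Character(ch.id, ch.kind, ch.source_columns, flags)
        )
    return CharacterMatrix(
        locus_name=aln.locus_name,
        characters=tuple(flagged),
        samples=aln.samples,
        states=states,
        events=tuple(events),
    )


def diagnostic_sites(
    cm: CharacterMatrix,
    group_a: Iterable[str],
    group_b: Iterable[str],
) -> DiagnosticTable:
    """Fixed differences between two groups of haplotype-role rows."""
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise DataError(f"{cm.locus_name}: both groups must be non-empty")
    for sid in (*group_a, *group_b):
        if cm.record(sid).role is not Role.HAPLOTYPE:
            raise RoleError(
                f"{cm.locus_name}: {sid} is not a haplotype-role row; "
                "diploid consensus rows never define species alleles"
            )
    rows: list[DiagnosticSite] = []
    for k, ch in enumerate(cm.characters):
        a_all = [cm.states[sid][k] for sid in group_a]
        b_all = [cm.states[sid][k] for sid in group_b]
        a_states = set(a_all) - {"N"}
        b_states = set(b_all) - {"N"}
        if not a_states or not b_states:
            warnings.warn(
                f"{cm.locus_name}/{ch.id}: a group is empty after "
                "missing-data filtering; character skipped",
                stacklevel=2,
            )
            continue
        if len(a_states) == 1 and len(b_states) == 1 and a_states != b_states:
            flags = (
                ("missing_data",)
                if "N" in a_all or "N" in b_all
                else ()
            )
            rows.append(
                DiagnosticSite(
                    character_id=ch.id,
                    kind=ch.kind,
                    allele_a=next(iter(a_states)),
                    allele_b=next(iter(b_states)),
                    flags=flags,
                )
            )
    rows.sort(key=lambda r: r.character_id)
    return DiagnosticTable(locus_name=cm.locus_name, rows=tuple(rows))


def collapse_haplotypes(
    cm: CharacterMatrix,
    taxon: Taxon,
    species_tag: str,
    locus_letter: str,
    name_map: Mapping[tuple[str, ...], str] | None = None,
) -> HaplotypePanel:
    """Merge identical haplotype-role state vectors into named haplotypes.

    Names are ``<species_tag><locus_letter><rank>`` with rank by descending
    total count then first occurrence (``aA1`` = commonest species-A
    haplotype at locus A), unless ``name_map`` supplies names per vector.
    """
    rows = [
        s for s in cm.samples if s.role is Role.HAPLOTYPE and s.taxon is taxon
    ]
    if not rows:
        raise DataError(
            f"{cm.locus_name}: no haplotype-role rows for {taxon.value}"
        )
    order: dict[tuple[str, ...], int] = {}
    tallies: dict[tuple[str, ...], int] = {}
    pop_counts: dict[tuple[tuple[str, ...], str], int] = {}
    for i, rec in enumerate(rows):
        vec = cm.states[rec.sample_id]
        if set(vec) & AMBIGUITY_CODES:
            raise RoleError(
                f"{cm.locus_name}/{rec.sample_id}: ambiguity codes in a "
                "haplotype-role row"
            )
        order.setdefault(vec, i)
        tallies[vec] = tallies.get(vec, 0) + 1
        key = (vec, rec.population)
        pop_counts[key] = pop_counts.get(key, 0) + 1

    ranked = sorted(tallies, key=lambda v: (-tallies[v], order[v]))
    haplotypes = []
    counts: dict[tuple[str, str], int] = {}
    for rank, vec in enumerate(ranked, start=1):
        name = (
            name_map[vec]
            if name_map and vec in name_map
            else f"{species_tag}{locus_letter}{rank}"
        )
        haplotypes.append(Haplotype(name=name, states=vec, species=taxon))
        for (v, pop), n in pop_counts.items():
            if v == vec:
                counts[(pop, name)] = counts.get((pop, name), 0) + n
    return HaplotypePanel(
        locus_name=cm.locus_name,
        haplotypes=tuple(haplotypes),
        counts=counts,
    )


def merge_panels(*panels: HaplotypePanel) -> HaplotypePanel:
    """Union of panels (e.g. both parental species) sharing one schema."""
    if not panels:
        raise DataError("merge_panels needs at least one panel")
    haplotypes: list[Haplotype] = []
    counts: dict[tuple[str, str], int] = {}
    seen: set[str] = set()
    for panel in panels:
        for h in panel.haplotypes:
            if h.name in seen:
                raise DataError(f"duplicate haplotype name {h.name}")
            seen.add(h.name)
            haplotypes.append(h)
        for key, v in panel.counts.items():
            counts[key] = counts.get(key, 0) + v
    return HaplotypePanel(panels[0].locus_name, tuple(haplotypes), counts)


def polymorphism_summary(panel: HaplotypePanel) -> pd.DataFrame:
    """Per-population sample size, haplotype number, frequencies and number
    of segregating characters; a TOTAL row pools all populations."""
    if not panel.haplotypes:
        raise DataError(f"{panel.locus_name}: empty panel")
    names = panel.names()
    vec = {h.name: h.states for h in panel.haplotypes}

    def _segregating(present: list[str]) -> int:
        if not present:
            return 0
        n_char = len(vec[present[0]])
        seg = 0
        for k in range(n_char):
            states = {vec[n][k] for n in present} - {"N"}
            if len(states) > 1:
                seg += 1
        return seg

    rows = []
    for pop in panel.populations() + ["TOTAL"]:
        if pop == "TOTAL":
            per = {n: panel.total_count(n) for n in names}
        else:
            per = {n: panel.counts.get((pop, n), 0) for n in names}
        n = sum(per.values())
        present = [h for h in names if per[h] > 0]
        row = {
            "population": pop,
            "n": n,
            "n_haplotypes": len(present),
            "n_segregating": _segregating(present),
        }
        for h in names:
            row[f"freq_{h}"] = per[h] / n if n else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
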