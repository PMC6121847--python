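"""Consensus CDS calling, ambiguity-aware translation, and variable-site reports.

Per-individual consensus sequences are called from site-level base counts:
sites with coverage below a minimum (default 10×) are masked to N; sites
whose minor-allele frequency exceeds a noise threshold (default 0.35) are
scored as heterozygotes with the two-base IUPAC code; otherwise the majority
base is called.  Only two-fold ambiguity codes are emitted (diploid
assumption); a third allele above the noise threshold, or a tie for the
major allele among three bases, yields N with a warning.  Pileups are
assumed gap-free against the reference CDS (indels are out of scope).

Translation expands codons containing a single two-fold ambiguity into both
resolved codons, so a heterozygous site can contribute two amino-acid
states; codons containing N translate to X.  A site is "variable within
species" when conspecific individuals — pooled across populations — carry at
least two amino-acid states, heterozygotes contributing both of theirs.
Residue positions can be renumbered against bovine rhodopsin (RH1) through
a user-supplied per-gene alignment table, the field's convention for
comparing opsin tuning sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Data.IUPACData import ambiguous_dna_values

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")

#: two-base IUPAC ambiguity codes, e.g. {"A","G"} -> "R"
_TWOFOLD = {
    frozenset(bases): code
    for code, bases in ambiguous_dna_values.items()
    if len(bases) == 2
}

_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"


@dataclass(frozen=True)
class PileupColumn:
    """Base counts at one 1-based CDS position."""

    position: int
    a: int
    c: int
    g: int
    t: int

    @property
    def coverage(self) -> int:
        return self.a + self.c + self.g + self.t

    def counts(self) -> dict[str, int]:
        return {"A": self.a, "C": self.c, "G": self.g, "T": self.t}


@dataclass
class ConsensusSequence:
    """Per-individual consensus CDS and its ambiguity-aware translation."""

    individual: str
    gene: str
    nucleotides: str
    protein_states: list[frozenset[str]] = field(repr=False)

    @property
    def protein(self) -> str:
        """Protein string; heterozygous sites rendered as e.g. ``{I/M}``."""
        return "".join(
            next(iter(s)) if len(s) == 1 else "{" + "/".join(sorted(s)) + "}"
            for s in self.protein_states
        )


def call_base(column: PileupColumn, min_coverage: int = 10, noise_threshold: float = 0.35) -> str:
    """Call one consensus base from a pileup column.

    Coverage below ``min_coverage`` masks to N.  Otherwise, if the
    second-most-frequent base exceeds ``noise_threshold`` of the coverage,
    the site is a heterozygote and gets the two-base IUPAC code; if a third
    base also exceeds the threshold, or three bases tie for the majority,
    the call is N (only diploid, two-fold ambiguity is supported).  The
    call depends only on base frequencies, so it is invariant to scaling
    all counts at a column.
    """
    cov = column.coverage
    if cov < min_coverage:
        return "N"
    counts = column.counts()
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    top, second, third = ranked[0], ranked[1], ranked[2]
    if top[1] == second[1] == third[1]:
        logger.warning(
            "position %d: three-way tie for major allele; calling N", column.position
        )
        return "N"
    if third[1] / cov > noise_threshold:
        logger.warning(
            "position %d: >2 alleles above noise threshold; calling N", column.position
        )
        return "N"
    if second[1] / cov > noise_threshold:
        return _TWOFOLD[frozenset({top[0], second[0]})]
    return top[0]


def call_consensus(
    columns: list[PileupColumn],
    min_coverage: int = 10,
    noise_threshold: float = 0.35,
) -> str:
    """Consensus nucleotide sequence from pileup columns covering 1..L.

    Columns must cover every position 1..L exactly once (missing positions
    are an error; supply zero-count columns for uncovered sites, which mask
    to N).
    """
    by_pos = {col.position: col for col in columns}
    length = max(by_pos) if by_pos else 0
    if len(by_pos) != len(columns):
        raise ValueError("duplicate pileup positions")
    missing = [p for p in range(1, length + 1) if p not in by_pos]
    if missing:
        raise ValueError(f"pileup does not cover contiguous 1..{length}: missing {missing[:5]}")
    return "".join(
        call_base(by_pos[p], min_coverage, noise_threshold) for p in range(1, length + 1)
    )


def _resolve_codon(codon: str) -> frozenset[str]:
    """Amino-acid state set for a codon that may contain N or one ambiguity code."""
    if "N" in codon:
        return frozenset("X")
    ambiguous = [i for i, b in enumerate(codon) if b not in BASES]
    if not ambiguous:
        return frozenset(_CODON_TABLE[codon])
    if len(ambiguous) > 1:
        # two het positions in one codon: phase unknown, report X
        return frozenset("X")
    i = ambiguous[0]
    code = codon[i]
    expansion = ambiguous_dna_values.get(code, "")
    if len(expansion) != 2:
        return frozenset("X")
    return frozenset(_CODON_TABLE[codon[:i] + b + codon[i + 1 :]] for b in expansion)


def translate(cds: str) -> list[frozenset[str]]:
    """Translate a consensus CDS into per-codon amino-acid state sets.

    Standard genetic code.  Codons with one two-fold IUPAC ambiguity expand
    into both resolved codons (up to two states per site); codons containing
    N yield {X}.  An internal stop is flagged with a warning and translation
    continues with '*'.  Length must be divisible by 3.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    states = [_resolve_codon(cds[i : i + 3]) for i in range(0, len(cds), 3)]
    for idx, s in enumerate(states[:-1]):
        if "*" in s:
            logger.warning("internal stop codon at codon %d", idx + 1)
    return states


@dataclass
class AASiteReport:
    """One amino-acid site with >=2 states among conspecific individuals."""

    gene: str
    species: str
    cds_codon_index: int  # 1-based
    rh1_position: int | None
    rh1_mapped: bool
    states: frozenset[str]
    population_states: dict[str, frozenset[str]]


def variable_sites_within_species(
    consensi: list[tuple[str, str, ConsensusSequence]],
    offset_map: dict[int, int] | None = None,
) -> list[AASiteReport]:
    """Report amino-acid sites variable within species.

    ``consensi`` is a list of (species, population, ConsensusSequence) for
    one gene.  A site is reported when, pooling all populations of a
    species, conspecific individuals carry >= 2 distinct amino-acid states;
    heterozygous individuals contribute both states.  All-X columns are
    skipped.  ``offset_map`` (codon index -> bovine RH1 residue) renumbers
    reported sites; unmapped positions keep the raw index and are flagged.
    """
    genes = {c.gene for _, _, c in consensi}
    if len(genes) > 1:
        raise ValueError(f"consensi mix genes {sorted(genes)}; report one gene at a time")
    gene = genes.pop() if genes else ""
    reports: list[AASiteReport] = []
    by_species: dict[str, list[tuple[str, ConsensusSequence]]] = {}
    for species, population, cons in consensi:
        by_species.setdefault(species, []).append((population, cons))

    for species in sorted(by_species):
        members = by_species[species]
        lengths = {len(c.protein_states) for _, c in members}
        if len(lengths) != 1:
            raise ValueError(f"species {species}: unequal protein lengths {sorted(lengths)}")
        n_codons = lengths.pop()
        for idx in range(n_codons):
            site_states: set[str] = set()
            pop_states: dict[str, set[str]] = {}
            for population, cons in members:
                observed = set(cons.protein_states[idx]) - {"X"}
                site_states |= observed
                pop_states.setdefault(population, set()).update(observed)
            if len(site_states) < 2:
                continue
            rh1_pos, mapped = map_to_bovine_rh1(idx + 1, offset_map)
            reports.append(
                AASiteReport(
                    gene=gene,
                    species=species,
                    cds_codon_index=idx + 1,
                    rh1_position=rh1_pos,
                    rh1_mapped=mapped,
                    states=frozenset(site_states),
                    population_states={
                        p: frozenset(s) for p, s in sorted(pop_states.items())
                    },
                )
            )
    return reports


def map_to_bovine_rh1(
    cds_codon_index: int, offset_map: dict[int, int] | None
) -> tuple[int, bool]:
    """Renumber a codon index against bovine RH1 via an alignment table.

    ``offset_map`` maps query codon index -> RH1 residue number.  Positions
    absent from the map (or a missing map) return the raw index flagged
    unmapped (``False``).
    """
    if offset_map is None:
        return cds_codon_index, False
    if not all(
        isinstance(k, int) and isinstance(v, int) for k, v in offset_map.items()
    ):
        raise ValueError("offset map must map int codon indices to int RH1 positions")
    if cds_codon_index in offset_map:
        return offset_map[cds_codon_index], True
    return cds_codon_index, False


def read_pileup(path: str | Path) -> dict[str, list[PileupColumn]]:
    """Read a pileup TSV (gene, position, A, C, G, T) into per-gene columns."""
    raw = pd.read_csv(path, sep="\t", comment="#")
    required = ("gene", "position", "A", "C", "G", "T")
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ValueError(f"pileup {path}: missing column(s) {missing}")
    out: dict[str, list[PileupColumn]] = {}
    for row in raw.itertuples(index=False):
        out.setdefault(str(row.gene), []).append(
            PileupColumn(
                position=int(row.position),
                a=int(row.A),
                c=int(row.C),
                g=int(row.G),
                t=int(row.T),
            )
        )
    return out


def read_offset_map(path: str | Path) -> dict[int, int]:
    """Read an alignment table TSV (codon_index, rh1_position)."""
    raw = pd.read_csv(path, sep="\t", comment="#")
    for col in ("codon_index", "rh1_position"):
        if col not in raw.columns:
            raise ValueError(f"offset map {path}: missing column {col!r}")
    try:
        return {
            int(r.codon_index): int(r.rh1_position) for r in raw.itertuples(index=False)
        }
    except (TypeError, ValueError) as exc:
        raise ValueError(f"offset map {path}: malformed row ({exc})") from exc


def site_report_frame(reports: list[AASiteReport]) -> pd.DataFrame:
    """Tidy TSV-ready view of variable-site reports."""
    rows = []
    for r in reports:
        rows.append(
            {
                "gene": r.gene,
                "species": r.species,
                "cds_codon_index": r.cds_codon_index,
                "rh1_position": r.rh1_position,
                "rh1_mapped": r.rh1_mapped,
                "states": "/".join(sorted(r.states)),
                "population_states": ";".join(
                    f"{p}={'/'.join(sorted(s))}" for p, s in r.population_states.items()
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "species",
            "cds_codon_index",
            "rh1_position",
            "rh1_mapped",
            "states",
            "population_states",
        ],
    )
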