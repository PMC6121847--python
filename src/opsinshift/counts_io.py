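"""Input/output for count tables, sample metadata, λmax tables, and spectra.

All tabular inputs are UTF-8 tab-separated files; lines starting with ``#``
are treated as comments.  Counting pipelines emit integers, so fractional
count values are rejected rather than rounded — silent rounding would hide
upstream errors.

The ``total_reads`` column is the per-sample count of all QC-passed reads
(the denominator of the cyp27c1 reads-per-million normalization).  Whether
that denominator should be raw or mapped reads is a choice the user makes
when producing the table; this module only requires it to be at least the
sum of the per-gene counts.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy.constants import c, h

logger = logging.getLogger(__name__)

#: The seven cone opsin paralogs, ordered from shortest to longest peak
#: absorption.  ``rh2ab`` is rh2aβ and ``rh2aa`` is rh2aα.
CONE_OPSINS: tuple[str, ...] = (
    "sws1",
    "sws2b",
    "sws2a",
    "rh2b",
    "rh2ab",
    "rh2aa",
    "lws",
)

#: Peak absorption (λmax, nm) of each cone opsin pigment.  Values for
#: sws2b…lws are from Midas cichlid measurements and sws1 from Nile tilapia.
_DEFAULT_LAMBDA_MAX: dict[str, float] = {
    "sws1": 360.0,
    "sws2b": 425.0,
    "sws2a": 456.0,
    "rh2b": 472.0,
    "rh2ab": 517.0,
    "rh2aa": 527.0,
    "lws": 560.0,
}

COUNT_COLUMNS: tuple[str, ...] = CONE_OPSINS + ("cyp27c1", "total_reads")


class Environment(str, enum.Enum):
    """Photic environment of a sampling site.

    Ordered by colonization history: rivers are ancestral, great lakes were
    colonized from rivers (colonization 1) and the crater lake from a great
    lake (colonization 2).
    """

    RIVER = "river"
    GREAT_LAKE = "great_lake"
    CRATER_LAKE = "crater_lake"

    @classmethod
    def parse(cls, label: str) -> "Environment":
        try:
            return cls(str(label).strip().lower())
        except ValueError:
            allowed = ", ".join(e.value for e in cls)
            raise ValueError(
                f"unknown environment {label!r}; allowed levels: {allowed}"
            ) from None


#: Colonization events as (ancestral, derived) environment pairs.
COLONIZATION_EVENTS: dict[str, tuple[Environment, Environment]] = {
    "colonization_1": (Environment.RIVER, Environment.GREAT_LAKE),
    "colonization_2": (Environment.GREAT_LAKE, Environment.CRATER_LAKE),
}


@dataclass(frozen=True)
class SampleRecord:
    """One sequenced individual: id, species, and photic environment."""

    sample_id: str
    species: str
    environment: Environment

    @property
    def population(self) -> str:
        """Population label, the species × environment combination."""
        return f"{self.species}:{self.environment.value}"


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-sample gene count table.

    The TSV must name ``sample_id``, the seven cone opsins, ``cyp27c1``
    and ``total_reads``.  Unknown columns are ignored with a warning.

    Returns a DataFrame indexed by ``sample_id`` with integer count columns.

    Raises
    ------
    ValueError
        On a missing column, a non-integer or negative count, a duplicate
        sample id, or a row whose per-gene counts exceed ``total_reads``.
    """
    raw = _read_tsv(path)
    required = ("sample_id",) + COUNT_COLUMNS
    missing = [col for col in required if col not in raw.columns]
    if missing:
        raise ValueError(f"count table {path}: missing column(s) {missing}")
    extra = [col for col in raw.columns if col not in required]
    if extra:
        logger.warning("count table %s: ignoring unknown column(s) %s", path, extra)

    dup = raw["sample_id"][raw["sample_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"count table {path}: duplicate sample id(s) {sorted(set(dup))}")

    table = raw[list(required)].set_index("sample_id")
    counts = pd.DataFrame(index=table.index)
    for col in COUNT_COLUMNS:
        numeric = pd.to_numeric(table[col], errors="raise")
        if (numeric % 1 != 0).any():
            bad = table.index[numeric % 1 != 0][0]
            raise ValueError(
                f"count table {path}: non-integer count in column {col!r}, sample {bad!r}"
            )
        counts[col] = numeric.astype(np.int64)

    for col in COUNT_COLUMNS:
        if (counts[col] < 0).any():
            bad = counts.index[counts[col] < 0][0]
            raise ValueError(
                f"count table {path}: negative count in column {col!r}, sample {bad!r}"
            )
    if (counts["total_reads"] <= 0).any():
        bad = counts.index[counts["total_reads"] <= 0][0]
        raise ValueError(f"count table {path}: total_reads must be positive (sample {bad!r})")

    gene_sum = counts[list(CONE_OPSINS) + ["cyp27c1"]].sum(axis=1)
    over = counts.index[gene_sum > counts["total_reads"]]
    if len(over):
        raise ValueError(
            f"count table {path}: gene counts exceed total_reads for sample {over[0]!r}"
        )
    return counts


def write_count_table(counts: pd.DataFrame, path: str | Path) -> None:
    """Write a count table TSV that :func:`read_count_table` round-trips."""
    out = counts.reset_index()
    if out.columns[0] != "sample_id":
        out = out.rename(columns={out.columns[0]: "sample_id"})
    out.to_csv(path, sep="\t", index=False)


def read_sample_metadata(path: str | Path) -> list[SampleRecord]:
    """Read sample metadata (sample_id, species, environment).

    Environment labels parse case-insensitively.  Duplicate sample ids and
    unknown environment levels are hard errors.
    """
    raw = _read_tsv(path)
    required = ("sample_id", "species", "environment")
    missing = [col for col in required if col not in raw.columns]
    if missing:
        raise ValueError(f"metadata {path}: missing column(s) {missing}")
    dup = raw["sample_id"][raw["sample_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"metadata {path}: duplicate sample id(s) {sorted(set(dup))}")
    return [
        SampleRecord(
            sample_id=row.sample_id,
            species=row.species,
            environment=Environment.parse(row.environment),
        )
        for row in raw.itertuples(index=False)
    ]


def metadata_frame(records: list[SampleRecord]) -> pd.DataFrame:
    """Tidy DataFrame view of sample records, indexed by sample id."""
    return pd.DataFrame(
        {
            "species": [r.species for r in records],
            "environment": [r.environment.value for r in records],
            "population": [r.population for r in records],
        },
        index=pd.Index([r.sample_id for r in records], name="sample_id"),
    )


def write_sample_metadata(records: list[SampleRecord], path: str | Path) -> None:
    frame = metadata_frame(records)[["species", "environment"]]
    frame.reset_index().to_csv(path, sep="\t", index=False)


def default_lambda_max() -> dict[str, float]:
    """The default λmax table (nm) for the seven cone opsins."""
    return dict(_DEFAULT_LAMBDA_MAX)


def read_lambda_max(path: str | Path) -> dict[str, float]:
    """Read an opsin → λmax (nm) TSV with columns ``opsin`` and ``lambda_max``.

    Exactly the seven cone opsins must be present and their λmax values must
    be strictly increasing in the order sws1 < sws2b < sws2a < rh2b < rh2ab
    < rh2aa < lws.
    """
    raw = _read_tsv(path)
    for col in ("opsin", "lambda_max"):
        if col not in raw.columns:
            raise ValueError(f"lambda_max table {path}: missing column {col!r}")
    table = {str(r.opsin): float(r.lambda_max) for r in raw.itertuples(index=False)}
    if set(table) != set(CONE_OPSINS):
        raise ValueError(
            f"lambda_max table {path}: must contain exactly the opsins {CONE_OPSINS}"
        )
    values = [table[o] for o in CONE_OPSINS]
    if not all(a < b for a, b in zip(values, values[1:])):
        raise ValueError(
            f"lambda_max table {path}: values must be strictly increasing in the "
            f"order {CONE_OPSINS}"
        )
    if min(values) <= 0:
        raise ValueError(f"lambda_max table {path}: λmax must be positive")
    return table


def write_lambda_max(table: dict[str, float], path: str | Path) -> None:
    pd.DataFrame(
        {"opsin": list(CONE_OPSINS), "lambda_max": [table[o] for o in CONE_OPSINS]}
    ).to_csv(path, sep="\t", index=False)


def read_irradiance(path: str | Path) -> pd.DataFrame:
    """Read an irradiance spectrum TSV (wavelength_nm, watts)."""
    raw = pd.read_csv(path, sep="\t", comment="#")
    for col in ("wavelength_nm", "watts"):
        if col not in raw.columns:
            raise ValueError(f"irradiance table {path}: missing column {col!r}")
    return raw[["wavelength_nm", "watts"]].astype(float)


def watts_to_photons(irradiance, wavelength_nm):
    """Convert spectral irradiance (W m⁻² nm⁻¹) to photon flux.

    A photon of wavelength λ carries energy E = hc/λ, so a power flux of
    ``irradiance`` watts corresponds to ``irradiance · λ/(hc)`` photons per
    second (λ in metres).  Returns photons s⁻¹ m⁻² nm⁻¹.  Accepts scalars or
    arrays; linear in both arguments.
    """
    irradiance = np.asarray(irradiance, dtype=float)
    wavelength_nm = np.asarray(wavelength_nm, dtype=float)
    if np.any(wavelength_nm <= 0):
        raise ValueError("wavelength must be positive")
    if np.any(irradiance < 0):
        raise ValueError("irradiance must be non-negative")
    out = irradiance * (wavelength_nm * 1e-9) / (h * c)
    return float(out) if out.ndim == 0 else out


def read_reference_cds(path: str | Path) -> dict[str, str]:
    """Read reference coding sequences from FASTA (wrapped or unwrapped)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
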