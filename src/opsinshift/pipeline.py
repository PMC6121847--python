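"""End-to-end orchestration: counts → profiles → rank stats → parallelism.

The pipeline is configured with a flat mapping (usually loaded from YAML),
writes one TSV per stage plus a JSON manifest (package version, seed,
parameter echo, SHA-256 of every written file), and is deterministic under
a fixed seed.  Stochastic stages require an explicit seed; a missing seed
is an error rather than a silent fresh draw.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

import opsinshift
from opsinshift import counts_io, expression, parallelism, rank_stats
from opsinshift.counts_io import Environment, metadata_frame

logger = logging.getLogger(__name__)

DEFAULT_MEASURES = (
    "single_cone_fraction",
    "rh2a_ratio",
    "lws_fraction",
    "sensitivity_index",
    "cyp_rel",
)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def compute_profiles(config: dict) -> pd.DataFrame:
    counts = counts_io.read_count_table(config["counts"])
    records = counts_io.read_sample_metadata(config["metadata"])
    lam = (
        counts_io.read_lambda_max(config["lambda_max"])
        if config.get("lambda_max")
        else counts_io.default_lambda_max()
    )
    return expression.profile_table(counts, metadata_frame(records), lam)


def compute_rank_stats(profiles: pd.DataFrame, config: dict) -> dict[str, pd.DataFrame]:
    """Scheirer-Ray-Hare per measure, per-species Kruskal-Wallis with FDR,
    and the rank-maintenance test of the sensitivity index per event."""
    measures = tuple(config.get("measures", DEFAULT_MEASURES))
    srh_rows = []
    for measure in measures:
        data = profiles[[measure, "species", "environment"]].dropna()
        res = rank_stats.scheirer_ray_hare(
            data[measure].to_numpy(), data["species"].to_numpy(), data["environment"].to_numpy()
        )
        frame = res.as_frame()
        frame.insert(0, "measure", measure)
        srh_rows.append(frame)
    srh = pd.concat(srh_rows, ignore_index=True)

    kw_measures = tuple(m for m in measures if m != "sensitivity_index")
    kw = rank_stats.per_species_kw_table(
        profiles, measures=kw_measures, fdr_family=config.get("fdr_family", "per-measure")
    )

    rm_rows = []
    pop_means = profiles.groupby(["species", "environment"])["sensitivity_index"].mean()
    for event, (anc, der) in counts_io.COLONIZATION_EVENTS.items():
        try:
            m1 = pop_means.xs(anc.value, level="environment")
            m2 = pop_means.xs(der.value, level="environment")
            shared = m1.index.intersection(m2.index)
            res = rank_stats.rank_maintenance(m1.loc[shared], m2.loc[shared])
            rm_rows.append(
                {"event": event, "rho": res.rho, "p": res.p, "n_species": res.n}
            )
        except (KeyError, ValueError) as exc:
            logger.warning("rank maintenance skipped for %s: %s", event, exc)
    return {"srh": srh, "kruskal_wallis": kw, "rank_maintenance": pd.DataFrame(rm_rows)}


def compute_parallelism(profiles: pd.DataFrame, config: dict) -> pd.DataFrame:
    if "seed" not in config:
        raise ValueError("parallelism stage requires an explicit seed")
    frames = []
    for scope in parallelism.SCOPES:
        res = parallelism.permutation_test(
            profiles,
            scope=scope,
            n_perm=int(config.get("n_perm", 999)),
            seed=int(config["seed"]),
            scale=config.get("scale", "sd"),
        )
        frames.append(res.as_frame())
    return pd.concat(frames, ignore_index=True)


def run_all(config: dict) -> dict[str, pd.DataFrame]:
    """Run the full analysis and write per-stage TSVs plus a manifest.

    ``config`` keys: counts, metadata, out_dir (required); lambda_max,
    measures, fdr_family, n_perm, seed, scale (optional; seed required for
    the parallelism stage).  Any stage failure aborts with the stage name.
    """
    for key in ("counts", "metadata", "out_dir"):
        if key not in config:
            raise ValueError(f"pipeline config missing required key {key!r}")
    for key in ("counts", "metadata", "lambda_max"):
        if config.get(key) and not Path(config[key]).exists():
            raise FileNotFoundError(f"input file for {key!r} not found: {config[key]}")

    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict[str, pd.DataFrame] = {}

    stage = "profiles"
    try:
        profiles = compute_profiles(config)
        results["profiles"] = profiles
        stage = "rank_stats"
        results.update(compute_rank_stats(profiles, config))
        stage = "parallelism"
        results["parallelism"] = compute_parallelism(profiles, config)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    written = {}
    for name, frame in results.items():
        path = out_dir / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=(name == "profiles"))
        written[name] = path

    manifest = {
        "package": "opsinshift",
        "version": opsinshift.__version__,
        "seed": config.get("seed"),
        "parameters": {
            k: v for k, v in config.items() if k not in {"counts", "metadata", "out_dir"}
        },
        "inputs": {k: str(config[k]) for k in ("counts", "metadata") if k in config},
        "outputs": {name: _sha256(path) for name, path in written.items()},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return results
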