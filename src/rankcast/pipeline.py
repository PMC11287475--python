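"""Pipeline orchestration: fit -> score -> rank (-> simulate) with provenance.

A single config (YAML/JSON-compatible dict) drives all stages.  Per-stage
seeds are derived from one root seed by fixed offsets, outputs land in a run
directory, and a manifest (config hash, seeds, input digests, package
version, per-stage outputs) makes reruns byte-for-byte reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .abm import SimConfig, SpeciesSpec, ToxinSpec, run_simulation, species_growth_rate
from .growth import fit_plate, read_plate_csv, write_params_csv
from .ranking import predict_rank, rank_from_monoculture, slow_growers
from .supernatant import (
    integrative_supernatant_score,
    matrix_from_params,
    scores_to_frame,
    strong_inhibition_edges,
)
from .synth import generate_plate, gim_like_spec

log = logging.getLogger("rankcast")

#: fixed per-stage seed offsets from the root seed
SEED_OFFSETS = {"synth": 0, "simulate": 1}

DEFAULT_CONFIG = {
    "seed": 0,
    "plate_csv": None,  # path; when None, synthetic GIM-like data are generated
    "metric": "inv_tmid",
    "tie_tol": 0.05,
    "inhibition_threshold": 0.20,
    "medium": None,
    "simulate": False,
    "sim_steps": 5000,
}


class PipelineError(RuntimeError):
    pass


def _hash_obj(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def aggregate_params(params: pd.DataFrame, metric: str) -> dict[str, float]:
    """Per-species mean of a growth metric over converged plain-monoculture wells."""
    ok = params[params["converged"] & (params["treatment"] == "plain")]
    if ok.empty:
        raise PipelineError("no converged plain-monoculture wells to rank from")
    return ok.groupby("species")[metric].mean().to_dict()


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute all stages; returns the manifest (also written to manifest.json)."""
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict = {
        "package_version": __version__,
        "config": cfg,
        "config_hash": _hash_obj(cfg),
        "seeds": {k: seed + v for k, v in SEED_OFFSETS.items()},
        "inputs": {},
        "stages": {},
    }

    def stage(name: str):
        t0 = time.perf_counter()
        log.info("stage %s: start", name)

        def done(outputs: dict):
            manifest["stages"][name] = {
                "outputs": outputs,
                "elapsed_s": round(time.perf_counter() - t0, 3),
            }
            log.info("stage %s: done (%.2fs)", name, time.perf_counter() - t0)

        return done

    try:
        # --- input stage: load or synthesize the plate
        done = stage("plate")
        if cfg["plate_csv"]:
            plate_path = Path(cfg["plate_csv"])
            if not plate_path.exists():
                raise PipelineError(f"plate stage: input {plate_path} does not exist")
            manifest["inputs"]["plate_csv"] = _hash_file(plate_path)
            curves = read_plate_csv(plate_path)
        else:
            spec = gim_like_spec(seed=manifest["seeds"]["synth"])
            plate = generate_plate(spec)
            plate_path = out / "plate.csv"
            plate.to_csv(plate_path, index=False, float_format="%.8g")
            curves = read_plate_csv(plate_path)
        done({"plate_csv": str(plate_path)})

        # --- fit stage
        done = stage("fit")
        params = fit_plate(curves)
        params_path = out / "params.csv"
        write_params_csv(params, params_path)
        done({"params_csv": str(params_path)})

        # --- supernatant stage
        done = stage("supernatant")
        matrix = matrix_from_params(params, parameter=cfg["metric"], medium=cfg["medium"])
        matrix.values.to_csv(out / "supernatant_matrix.csv", float_format="%.10g")
        scores = integrative_supernatant_score(matrix)
        scores_to_frame(scores).to_csv(
            out / "supernatant_scores.csv", index=False, float_format="%.10g"
        )
        edges = strong_inhibition_edges(matrix, threshold=cfg["inhibition_threshold"])
        done(
            {
                "matrix_csv": str(out / "supernatant_matrix.csv"),
                "scores_csv": str(out / "supernatant_scores.csv"),
                "edges": [list(e) for e in edges],
            }
        )

        # --- rank stage
        done = stage("rank")
        values = aggregate_params(params, cfg["metric"])
        mono = rank_from_monoculture(values, metric=cfg["metric"], tie_tol=cfg["tie_tol"])
        slow = slow_growers(mono)
        predicted = predict_rank(mono, edges, slow)
        rank_json = {
            "metric": cfg["metric"],
            "monoculture_values": {k: float(v) for k, v in sorted(values.items())},
            "mono_rank": [list(g) for g in mono.groups],
            "slow_growers": sorted(slow),
            "strong_inhibition_edges": [list(e) for e in edges],
            "predicted_rank": [list(g) for g in predicted.groups],
            "predicted_rank_str": str(predicted),
        }
        (out / "predicted_rank.json").write_text(json.dumps(rank_json, indent=2) + "\n")
        done({"rank_json": str(out / "predicted_rank.json")})

        # --- optional simulate stage
        if cfg["simulate"]:
            done = stage("simulate")
            tmids = {s: 1.0 / v for s, v in values.items()}
            ref = min(tmids.values())
            species = tuple(
                SpeciesSpec(s, species_growth_rate(ref, tmids[s])) for s in sorted(tmids)
            )
            toxins = tuple(ToxinSpec(p, (r,), theta=2500.0) for p, r in edges)
            sim_cfg = SimConfig(
                species=species,
                toxins=toxins,
                n_steps=int(cfg["sim_steps"]),
                seed=manifest["seeds"]["simulate"],
            )
            res = run_simulation(sim_cfg)
            pd.DataFrame(
                res.fractions_over_time, columns=res.species_labels
            ).to_csv(out / "sim_fractions.csv", index_label="step", float_format="%.8g")
            summary = pd.DataFrame(
                {
                    "species": res.species_labels,
                    "mean_fraction": res.mean_fraction,
                    "per_capita_toxin_uptake": res.per_capita_toxin_uptake,
                }
            )
            summary.to_csv(out / "sim_summary.csv", index=False, float_format="%.8g")
            done(
                {
                    "fractions_csv": str(out / "sim_fractions.csv"),
                    "summary_csv": str(out / "sim_summary.csv"),
                }
            )
    except PipelineError:
        raise
    except Exception as exc:  # tag the failing stage for the caller
        failed = len(manifest["stages"])
        names = ["plate", "fit", "supernatant", "rank", "simulate"]
        name = names[failed] if failed < len(names) else "unknown"
        raise PipelineError(f"{name} stage: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
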