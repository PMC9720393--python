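"""End-to-end pipeline: survey → phytosociology → diversity → ordination
→ driver attribution → year trends, with a reproducibility manifest.

A single global seed is fanned out to per-stage child streams through a
counter-based ``SeedSequence`` spawn, so each stage is individually
reproducible and insensitive to how much randomness earlier stages
consumed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diversity import diversity_profile
from .drivers import ABTConfig, abt_relative_influence
from .fixtures import load_occurrence_fixture
from .io import read_practices, read_survey, write_practices, write_survey
from .ordination import bray_curtis, community_matrix, nmds, permanova
from .phytosociology import guild_composition, rank_dominants, stratum_tables
from .simulate import SimulationDesign, generate_dataset
from .trends import year_trends
from .types import ValidationError

logger = logging.getLogger("seedbank")

STAGES = ("phytosociology", "diversity", "ordination", "drivers", "trends")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Either ``survey_path``/``practices_path`` point at existing CSV
    files, or ``design`` describes a synthetic survey to generate.
    """

    output_dir: str = "seedbank_results"
    rng_seed: int = 0
    survey_path: str | None = None
    practices_path: str | None = None
    design: SimulationDesign | None = None
    stages: tuple[str, ...] = STAGES
    evenness_variant: str = "modified_hill"
    n_nmds_runs: int = 250
    n_permutations: int = 999
    abt: ABTConfig = field(default_factory=ABTConfig)
    trends_by_mode: bool = False

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "design" in raw and isinstance(raw["design"], dict):
            raw["design"] = SimulationDesign(**raw["design"])
        if "abt" in raw and isinstance(raw["abt"], dict):
            raw["abt"] = ABTConfig(**raw["abt"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages; returns the manifest dictionary.

    All stage outputs are written as CSV/JSON into ``cfg.output_dir``;
    the manifest records the seed, the full configuration, a hash of the
    input survey and the files each stage produced.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed_seq = np.random.SeedSequence(cfg.rng_seed)
    child_seeds = {name: s for name, s in zip(("simulate",) + STAGES, seed_seq.spawn(len(STAGES) + 1))}
    manifest: dict = {
        "package_version": __version__,
        "rng_seed": cfg.rng_seed,
        "config": _jsonable(cfg),
        "stages": {},
    }

    t0 = time.time()
    if cfg.survey_path is not None:
        if cfg.practices_path is None and "drivers" in cfg.stages:
            raise ValidationError("drivers stage needs a practices table")
        quadrats = read_survey(cfg.survey_path)
        practices = read_practices(cfg.practices_path) if cfg.practices_path else []
    elif cfg.design is not None:
        rng = np.random.default_rng(child_seeds["simulate"])
        quadrats, practices, _ = generate_dataset(cfg.design, rng)
        write_survey(quadrats, out / "survey.csv")
        write_practices(practices, out / "practices.csv")
        manifest["stages"]["simulate"] = {
            "n_quadrats": len(quadrats),
            "n_sites": len(practices),
            "files": ["survey.csv", "practices.csv"],
        }
    else:
        raise ValidationError("config needs either survey_path or a simulation design")
    survey_hash = hashlib.sha256(
        pd.util.hash_pandas_object(
            pd.DataFrame([(q.site_id, q.field_id, q.quadrat_id, sp, n)
                          for q in quadrats for sp, n in sorted(q.counts.items())])
        ).to_numpy().tobytes()
    ).hexdigest()
    manifest["survey_sha256"] = survey_hash
    logger.info("loaded %d quadrats in %.2fs", len(quadrats), time.time() - t0)

    _, pool = load_occurrence_fixture()
    guild_map = {s.species_id: s.guild for s in pool}
    for q in quadrats:  # synthetic pools use ids of the form guild_NN
        for sp in q.counts:
            if sp not in guild_map:
                guild_map[sp] = sp.rsplit("_", 1)[0]

    mode_tables = None
    field_cm = None
    profile = None

    for stage in cfg.stages:
        t0 = time.time()
        try:
            if stage == "phytosociology":
                mode_tables = stratum_tables(quadrats, by="mode")
                combined = pd.concat(mode_tables.values())
                combined.to_csv(out / "phytosociology_mode.csv")
                comp = pd.DataFrame(
                    {m: guild_composition(t, guild_map) for m, t in mode_tables.items()}
                )
                comp.to_csv(out / "guild_composition.csv")
                dominants = {m: rank_dominants(t, 10) for m, t in mode_tables.items()}
                (out / "dominant_species.json").write_text(json.dumps(dominants, indent=2))
                manifest["stages"][stage] = {
                    "n_strata": len(mode_tables),
                    "files": ["phytosociology_mode.csv", "guild_composition.csv",
                              "dominant_species.json"],
                }
            elif stage == "diversity":
                profile = diversity_profile(quadrats, cfg.evenness_variant)
                profile.to_csv(out / "diversity.csv", index=False)
                manifest["stages"][stage] = {
                    "n_quadrats": len(profile),
                    "files": ["diversity.csv"],
                }
            elif stage == "ordination":
                field_cm = community_matrix(quadrats, practices or None)
                d = bray_curtis(field_cm.values)
                d.to_csv(out / "bray_curtis.csv")
                rng = np.random.default_rng(child_seeds["ordination"])
                res = nmds(d, n_runs=cfg.n_nmds_runs, rng=rng)
                coords = res.coords.join(field_cm.meta)
                coords.to_csv(out / "nmds_coords.csv")
                perm = permanova(d, field_cm.meta["mode"].to_numpy(),
                                 n_perm=cfg.n_permutations, rng=rng)
                summary = {
                    "stress": res.stress,
                    "nmds_converged": res.converged,
                    "n_runs": res.n_runs,
                    "best_run_seed": res.best_run_seed,
                    "pseudo_F": perm.pseudo_F,
                    "R2": perm.R2,
                    "p_value": perm.p_value,
                    "n_permutations": perm.n_permutations,
                }
                (out / "ordination_summary.json").write_text(json.dumps(summary, indent=2))
                manifest["stages"][stage] = {
                    **summary,
                    "files": ["bray_curtis.csv", "nmds_coords.csv",
                              "ordination_summary.json"],
                }
            elif stage == "drivers":
                if not practices:
                    raise ValidationError("drivers stage needs a practices table")
                if field_cm is None:
                    field_cm = community_matrix(quadrats, practices)
                field_tables = stratum_tables(quadrats, by="field")
                shares = pd.DataFrame(
                    {lab: guild_composition(t, guild_map) for lab, t in field_tables.items()}
                ).T
                rng = np.random.default_rng(child_seeds["drivers"])
                abt = abt_relative_influence(practices, shares, cfg.abt, rng)
                table = abt.per_response.copy()
                table["aggregated"] = abt.influence
                table.to_csv(out / "abt_influence.csv")
                manifest["stages"][stage] = {
                    "top_predictor": abt.ranked().index[0],
                    "top_influence_pct": float(abt.ranked().iloc[0]),
                    "files": ["abt_influence.csv"],
                }
            elif stage == "trends":
                if profile is None:
                    profile = diversity_profile(quadrats, cfg.evenness_variant)
                if not practices:
                    raise ValidationError("trends stage needs consecutive-years metadata")
                results = year_trends(profile, practices, by_mode=cfg.trends_by_mode)
                rows = []
                for r in results:
                    for cls, row in r.class_stats.iterrows():
                        rows.append({
                            "response": r.response, "class": cls, "n": row["n"],
                            "mean": row["mean"], "sd": row["sd"],
                            "letters": row["letters"], "F": r.F,
                            "p_value": r.p_value, "transform": r.transform or "",
                        })
                pd.DataFrame(rows).to_csv(out / "trends.csv", index=False)
                manifest["stages"][stage] = {
                    "n_tests": len(results),
                    "files": ["trends.csv"],
                }
            else:
                raise ValidationError(f"unknown stage {stage!r}")
        except ValidationError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate failing stage
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        logger.info("stage %s done in %.2fs", stage, time.time() - t0)

    manifest["config_sha256"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()
    (out / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=2))
    return manifest
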