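"""End-to-end orchestration: synth -> GAN -> fidelity -> bench -> sOR.

One :class:`RunConfig` (YAML-serializable) drives the whole analysis and a
manifest records every seed, stage output and content hash, so a rerun with
the same config reproduces identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import fidelity as fidelity_mod
from . import gan as gan_mod
from . import bench as bench_mod
from . import sor as sor_mod
from .preprocess import encode, split

log = logging.getLogger(__name__)

STAGES = ("synth", "gan", "fidelity", "bench", "sor")


@dataclass
class RunConfig:
    outdir: str = "telepain_run"
    seeds: dict = field(default_factory=lambda: {"cohort": 1, "gan": 2, "bench": 3, "sor": 4})
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    cohort_spec: str | None = None  # YAML path; None -> default calibration
    n_patients: int = 218
    gan_epochs: int = 300
    sor_S: int = 200
    sor_R: int = 300

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: RunConfig) -> dict:
    """Execute the enabled stages in order and write a run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    fh.setLevel(logging.INFO)
    logging.getLogger().addHandler(fh)
    manifest = {"seeds": config.seeds, "stages": {}, "started": time.strftime("%Y-%m-%dT%H:%M:%S")}
    try:
        if config.cohort_spec:
            spec = cohort_mod.CohortSpec.from_yaml(config.cohort_spec)
        else:
            spec = cohort_mod.default_spec(n=config.n_patients, seed=config.seeds["cohort"])
        spec.to_yaml(out / "cohort_spec.yaml")

        real = None
        if config.stages.get("synth", True):
            log.info("stage synth: n=%d seed=%d", spec.n, config.seeds["cohort"])
            real = cohort_mod.sample_cohort(spec, seed=config.seeds["cohort"])
            cohort_mod.write_cohort(real, out / "real.csv")
            manifest["stages"]["synth"] = {"outputs": ["real.csv"]}

        fake = None
        if config.stages.get("gan", True):
            if real is None:
                real = cohort_mod.read_cohort(out / "real.csv")
            log.info("stage gan: epochs=%d seed=%d", config.gan_epochs, config.seeds["gan"])
            idx = split(len(real), 0.7, config.seeds["gan"])
            train_df = real.iloc[idx.train].reset_index(drop=True)
            test_df = real.iloc[idx.test].reset_index(drop=True)
            M, emap = encode(train_df)
            M_hold, _ = encode(test_df, emap)
            bundle = gan_mod.train(
                M,
                train_df["outcome"].to_numpy(),
                gan_mod.GanConfig(epochs=config.gan_epochs, seed=config.seeds["gan"]),
                emap,
                holdout=M_hold,
                holdout_labels=test_df["outcome"].to_numpy(),
            )
            bundle.save(out / "gan_bundle")
            fake = gan_mod.generate(bundle, len(real), seed=config.seeds["gan"])
            cohort_mod.write_cohort(fake, out / "fake.csv")
            manifest["stages"]["gan"] = {"outputs": ["fake.csv", "gan_bundle/training_log.csv"]}

        if config.stages.get("fidelity", True):
            real = real if real is not None else cohort_mod.read_cohort(out / "real.csv")
            fake = fake if fake is not None else cohort_mod.read_cohort(out / "fake.csv")
            report = fidelity_mod.compare_cohorts(real, fake)
            report.to_csv(out / "fidelity.csv", index=False)
            (out / "fidelity.txt").write_text(fidelity_mod.format_report(report) + "\n")
            pooled = pd.concat(
                [real.assign(source="real"), fake.assign(source="generated")], ignore_index=True
            )
            eff = fidelity_mod.age_effect(pooled)
            (out / "age_effect.json").write_text(
                json.dumps(
                    {
                        "odds_ratio_per_year": eff.odds_ratio_per_year,
                        "ci": list(eff.or_ci),
                        "age_p": eff.age_p,
                        "interaction_p": eff.interaction_p,
                    },
                    indent=1,
                )
            )
            manifest["stages"]["fidelity"] = {"outputs": ["fidelity.csv", "fidelity.txt", "age_effect.json"]}

        models = None
        if config.stages.get("bench", True):
            real = real if real is not None else cohort_mod.read_cohort(out / "real.csv")
            fake = fake if fake is not None else cohort_mod.read_cohort(out / "fake.csv")
            pooled = pd.concat([real, fake], ignore_index=True)
            log.info("stage bench: pooled n=%d seed=%d", len(pooled), config.seeds["bench"])
            table, models = bench_mod.run_bench(pooled, seed=config.seeds["bench"])
            table.to_csv(out / "bench.csv", index=False)
            manifest["stages"]["bench"] = {"outputs": ["bench.csv"]}

        if config.stages.get("sor", True):
            if models is None:
                raise RuntimeError("sor stage needs the bench stage (a trained model)")
            model = models["rf"]
            cfg = sor_mod.SORConfig(S=config.sor_S, R=config.sor_R, seed=config.seeds["sor"])
            summary = []
            for name, target, reference in sor_mod.condition_presets():
                res = sor_mod.compute_sor(model, target, reference, spec, cfg)
                res.as_frame().to_csv(out / f"sor_{name}.csv", index=False)
                lo, hi = res.ci
                summary.append(
                    {"condition": name, "mean_sor": res.mean, "median_sor": res.median, "p2.5": lo, "p97.5": hi}
                )
                log.info("sor %s: mean=%.3f CI=[%.3f, %.3f]", name, res.mean, lo, hi)
            pd.DataFrame(summary).to_csv(out / "sor_summary.csv", index=False)
            manifest["stages"]["sor"] = {
                "outputs": [f"sor_{n}.csv" for n, _, _ in sor_mod.condition_presets()] + ["sor_summary.csv"]
            }
    except Exception as exc:
        manifest["failed"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise
    finally:
        logging.getLogger().removeHandler(fh)

    for stage, entry in manifest["stages"].items():
        entry["sha256"] = {f: _sha256(out / f) for f in entry["outputs"]}
    skipped = [s for s in STAGES if not config.stages.get(s, True)]
    if skipped:
        manifest["skipped"] = skipped
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
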