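"""End-to-end orchestration: seeded, logged, reproducible study runs.

A study run builds the stimulus bundles for the requested grammar
variants, computes the predictor features, simulates a trained and a
control group per variant, runs the analysis battery, and writes
everything as plain CSV/JSON under an output directory together with
a config snapshot and a manifest of content hashes.  Three named seed
streams (stimuli / participants / analysis) let stimulus sets be held
fixed while participant draws vary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import CorpusStatistics, feature_matrix
from .grammar import VARIANTS
from .inference import (
    accuracy_table,
    dienes_bf,
    fit_all_participants,
    group_coefficient_tests,
    mixed_anova_2x2,
    participant_accuracy,
    pdp_confidence_analysis,
)
from .simulate import (
    PRESETS,
    make_participant,
    simulate_category_test,
    simulate_group,
)
from .stimuli import DEFAULT_LEXICON, StimulusSet, build_stimulus_set

__all__ = ["RunConfig", "run_study", "make_fixtures"]

log = logging.getLogger("aglab")


@dataclass
class RunConfig:
    """Everything a study run needs, round-trippable through YAML."""

    variants: tuple[str, ...] = VARIANTS
    seed_stimuli: int = 1
    seed_participants: int = 2
    seed_analysis: int = 3
    n_trained: int = 20
    n_control: int = 20
    trained_preset: str = "grammar-learner"
    control_preset: str = "control"
    out_dir: str = "study_out"
    verbosity: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["variants"] = tuple(data["variants"])
        return cls(**data)


def _stimulus_frame(design: StimulusSet) -> pd.DataFrame:
    rows = []
    for kind, sentences in (
        ("training", design.training),
        ("control-training", design.control_training),
    ):
        for s in sentences:
            rows.append({"role": kind, "pair_id": None, **s.to_record()})
    for p in design.pairs:
        for member in (p.grammatical, p.ungrammatical):
            rows.append(
                {"role": "test", "pair_id": p.pair_id, **member.to_record()}
            )
    return pd.DataFrame(rows)


def _assert_counts(design: StimulusSet) -> dict[str, int]:
    """The build-time count assertions of the study design."""
    counts = {
        "structures": len(design.structures),
        "old_structures": len(design.old),
        "new_structures": len(design.new),
        "training_sentences": len(design.training),
        "control_sentences": len(design.control_training),
        "test_pairs": len(design.pairs),
        "layer_violations": sum(
            1
            for p in design.pairs
            if p.ungrammatical.status == "layer-ungrammatical"
        ),
        "random_ungrammatical": sum(
            1
            for p in design.pairs
            if p.ungrammatical.status == "random-ungrammatical"
        ),
        "old_grammatical_items": sum(
            1 for p in design.pairs if p.grammatical.status == "old-grammatical"
        ),
        "new_grammatical_items": sum(
            1 for p in design.pairs if p.grammatical.status == "new-grammatical"
        ),
    }
    expected = {
        "structures": 18,
        "old_structures": 10,
        "new_structures": 8,
        "training_sentences": 168,
        "control_sentences": 168,
        "test_pairs": 66,
        "layer_violations": 44,
        "random_ungrammatical": 22,
        "old_grammatical_items": 39,
        "new_grammatical_items": 27,
    }
    for key, want in expected.items():
        if counts[key] != want:
            raise AssertionError(
                f"design constraint violated for {design.variant}: "
                f"{key} = {counts[key]}, expected {want}"
            )
        log.info("%s: %s = %d (ok)", design.variant, key, counts[key])
    return counts


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_study(config: RunConfig) -> Path:
    """Run the full synthetic study and write the artifact directory.

    Deterministic given the config seeds: the same config produces
    byte-identical CSV outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    config.to_yaml(out / "config.yaml")

    rng_participants = np.random.default_rng(config.seed_participants)
    rng_analysis = np.random.default_rng(config.seed_analysis)

    all_records = []
    all_counts = {}
    for i, variant in enumerate(config.variants):
        design = build_stimulus_set(variant, config.seed_stimuli + i)
        all_counts[variant] = _assert_counts(design)
        stats = CorpusStatistics.from_corpus(design.training)
        fm = feature_matrix(design.pairs, stats, "chunk-rep")
        fm4 = feature_matrix(design.pairs, stats, "gapped")

        _stimulus_frame(design).to_csv(
            out / f"stimuli_{variant}.csv", index=False
        )
        fm.to_csv(out / f"features_chunk-rep_{variant}.csv")
        fm4.to_csv(out / f"features_gapped_{variant}.csv")

        trained = simulate_group(
            design,
            fm,
            config.n_trained,
            config.trained_preset,
            rng_participants,
            group="trained",
            id_prefix=f"{variant}-t",
        )
        control = simulate_group(
            design,
            fm,
            config.n_control,
            config.control_preset,
            rng_participants,
            group="control",
            id_prefix=f"{variant}-c",
        )
        records = pd.concat([trained, control], ignore_index=True)
        records.to_csv(out / f"responses_{variant}.csv", index=False)
        all_records.append(records)

        # category test, one run per participant
        cat_rows = []
        for pid, group, preset in [
            (p, "trained", config.trained_preset)
            for p in trained["participant"].unique()
        ] + [
            (p, "control", config.control_preset)
            for p in control["participant"].unique()
        ]:
            model = make_participant(preset, rng_participants)
            cat = simulate_category_test(model, DEFAULT_LEXICON, rng_participants)
            cat["participant"] = pid
            cat["group"] = group
            cat["variant"] = variant
            cat_rows.append(cat)
        pd.concat(cat_rows, ignore_index=True).to_csv(
            out / f"category_test_{variant}.csv", index=False
        )

        coefs = fit_all_participants(trained, fm, "chunk-rep")
        coefs.to_csv(out / f"coefficients_chunk-rep_{variant}.csv")
        group_coefficient_tests(coefs).to_csv(
            out / f"group_tests_chunk-rep_{variant}.csv"
        )
        coefs4 = fit_all_participants(trained, fm4, "gapped")
        coefs4.to_csv(out / f"coefficients_gapped_{variant}.csv")
        group_coefficient_tests(coefs4).to_csv(
            out / f"group_tests_gapped_{variant}.csv"
        )

    records = pd.concat(all_records, ignore_index=True)
    accuracy_table(records).to_csv(out / "accuracy_table.csv", index=False)
    pdp_confidence_analysis(records).to_csv(out / "pdp_confidence.csv")

    acc = participant_accuracy(records, by=["phase"])
    mixed_anova_2x2(acc, "accuracy", "phase", "group").to_csv(
        out / "anova_phase_by_training.csv", index=False
    )

    # Evidence summary: Bayes factor for the class-chunk-strength group
    # effect under a half-normal prediction of up to ~2 small effects
    # (prior sd on the coefficient-mean scale).
    pooled = pd.concat(
        [
            pd.read_csv(out / f"coefficients_chunk-rep_{v}.csv", index_col=0)
            for v in config.variants
        ]
    )
    g = group_coefficient_tests(pooled)
    bf = dienes_bf(
        g.loc["chunk_class", "mean"],
        g.loc["chunk_class", "se"],
        prior_sd=abs(g.loc["chunk_class", "mean"]) + g.loc["chunk_class", "se"],
    )
    summary = {
        "counts": all_counts,
        "pooled_group_tests": g.reset_index().to_dict(orient="records"),
        "bf_chunk_class": bf,
        "n_records": int(len(records)),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))

    manifest = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("study written to %s (%d files)", out, len(manifest))
    return out


def make_fixtures(size: str, seed: int, out_dir: str | Path) -> Path:
    """Packaged fixture runs: ``tiny`` (one grammar, 4 participants)
    for fast checks, ``full`` for the complete 8-group design."""
    if size == "tiny":
        config = RunConfig(
            variants=("centre-left",),
            seed_stimuli=seed,
            seed_participants=seed + 1,
            seed_analysis=seed + 2,
            n_trained=4,
            n_control=4,
            out_dir=str(out_dir),
        )
    elif size == "full":
        config = RunConfig(
            variants=VARIANTS,
            seed_stimuli=seed,
            seed_participants=seed + 1,
            seed_analysis=seed + 2,
            out_dir=str(out_dir),
        )
    else:
        raise ValueError("size must be 'tiny' or 'full'")
    path = run_study(config)
    manifest = json.loads((path / "manifest.json").read_text())
    manifest["_fixture"] = {"size": size, "seed": seed}
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return path
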