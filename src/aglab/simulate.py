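"""Simulated participants for the two-alternative grammaticality test.

Each synthetic participant chooses between the grammatical and the
ungrammatical member of a pair according to a logistic model over the
predictor differences: the evidence is ``e = w0 + w . x`` where ``x``
is the pair's feature-difference vector and ``w0`` (the intercept
weight) is the participant's sensitivity to nonlocal structure.  Under
inclusion instructions ("pick the familiar item") the grammatical
member is chosen with probability ``logistic(e)``.  Under exclusion
instructions ("pick the unfamiliar item") a participant reverses the
knowledge-driven choice with probability ``c`` -- the conscious
control parameter of the process-dissociation logic: ``c = 0`` leaves
exclusion identical to inclusion (purely unconscious knowledge),
``c = 1`` fully reverses it (fully conscious knowledge).

Confidence on the 50-100 scale is a saturating function of the
evidence magnitude, ``50 + 50 * tanh(gain * |e|)``; 50 means pure
guessing.  Only the guess-versus-confident split is consumed by the
awareness analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .features import PREDICTOR_SPECS
from .stimuli import Lexicon, StimulusSet, TestPair

__all__ = [
    "ParticipantModel",
    "PRESETS",
    "make_participant",
    "simulate_choice",
    "simulate_participant",
    "simulate_group",
    "simulate_category_test",
]


@dataclass(frozen=True)
class ParticipantModel:
    """One participant's sensitivities and response parameters."""

    weights: dict[str, float]  # feature name -> weight; "intercept" included
    conscious_control: float = 0.0  # P(reverse knowledge-driven choice
    # under exclusion)
    confidence_gain: float = 0.5  # evidence-magnitude -> confidence scale
    p_category: float = 1 / 3  # P(correct) per category-test trial

    def __post_init__(self) -> None:
        if not 0.0 <= self.conscious_control <= 1.0:
            raise ValueError("conscious_control must be in [0, 1]")
        if self.confidence_gain < 0:
            raise ValueError("confidence_gain must be non-negative")


@dataclass(frozen=True)
class ModelDistribution:
    """Population distribution of participant weights (independent
    normals per feature) plus shared response parameters."""

    mean: dict[str, float]
    sd: dict[str, float]
    conscious_control: float = 0.0
    confidence_gain: float = 0.5
    p_category: float = 1 / 3

    def draw(self, rng: np.random.Generator) -> ParticipantModel:
        w = {
            k: float(rng.normal(self.mean[k], self.sd.get(k, 0.0)))
            for k in self.mean
        }
        return ParticipantModel(
            weights=w,
            conscious_control=self.conscious_control,
            confidence_gain=self.confidence_gain,
            p_category=self.p_category,
        )


def _chunk_rep_features() -> tuple[str, ...]:
    return ("intercept",) + PREDICTOR_SPECS["chunk-rep"]


# Group-mean weights for the trained ("grammar-learner") preset follow
# the study's reported per-unit regression coefficients; the
# between-participant standard deviations are back-computed from the
# reported group t statistics (sd = |mean| * sqrt(n) / t at n = 80).
_GRAMMAR_LEARNER_MEAN = {
    "intercept": 0.150,
    "chunk_word": 0.004,
    "chunk_class": 0.002,
    "local_violation": 0.163,
    "rep_global_word": 0.032,
    "rep_global_class": -0.004,
    "rep_local_word": 0.170,
    "rep_local_class": -0.002,
}
_GRAMMAR_LEARNER_T = {
    "intercept": 2.43,
    "chunk_word": 1.11,
    "chunk_class": 2.30,
    "local_violation": 1.83,
    "rep_global_word": 3.98,
    "rep_global_class": -1.08,
    "rep_local_word": 3.15,
    "rep_local_class": -1.09,
}
_GRAMMAR_LEARNER_SD = {
    k: abs(m) * math.sqrt(80) / abs(_GRAMMAR_LEARNER_T[k])
    for k, m in _GRAMMAR_LEARNER_MEAN.items()
}

PRESETS: dict[str, ModelDistribution] = {
    # The intended generative model of a trained participant: logistic
    # over the full chunk/repetition/nonlocal feature set, with a small
    # amount of conscious control.
    "grammar-learner": ModelDistribution(
        mean=dict(_GRAMMAR_LEARNER_MEAN),
        sd=dict(_GRAMMAR_LEARNER_SD),
        conscious_control=0.1,
    ),
    # Same sensitivities, no conscious control: the correctly specified
    # generative model used for parameter recovery.
    "grammar-learner-implicit": ModelDistribution(
        mean=dict(_GRAMMAR_LEARNER_MEAN),
        sd=dict(_GRAMMAR_LEARNER_SD),
        conscious_control=0.0,
    ),
    # Identifiable-regime learner for validating the inference
    # machinery: per-feature weights sized so each predictor moves the
    # evidence by about 0.3 of its feature spread (keeping trials off
    # the deterministic ceiling where coefficients are only boundedly
    # identified), with moderate heterogeneity (CV = 0.5) and no
    # conscious control, i.e. a correctly specified generative model.
    "recovery": ModelDistribution(
        mean={
            "intercept": 0.15,
            "chunk_word": 0.004,
            "chunk_class": 0.0008,
            "local_violation": 0.163,
            "rep_global_word": 0.06,
            "rep_global_class": -0.03,
            "rep_local_word": 0.013,
            "rep_local_class": -0.02,
        },
        sd={
            "intercept": 0.075,
            "chunk_word": 0.002,
            "chunk_class": 0.0004,
            "local_violation": 0.08,
            "rep_global_word": 0.03,
            "rep_global_class": 0.015,
            "rep_local_word": 0.0065,
            "rep_local_class": 0.01,
        },
        conscious_control=0.0,
    ),
    # Mis-specified learner sensitive only to surface chunks: used to
    # test that the analysis can discriminate learner types.
    "chunk-learner": ModelDistribution(
        mean={
            "intercept": 0.0,
            "chunk_word": 0.008,
            "chunk_class": 0.0,
            "local_violation": 0.0,
            "rep_global_word": 0.0,
            "rep_global_class": 0.0,
            "rep_local_word": 0.0,
            "rep_local_class": 0.0,
        },
        sd={"chunk_word": 0.004},
        conscious_control=0.0,
    ),
    # Untrained control group: no knowledge at all.
    "control": ModelDistribution(
        mean={k: 0.0 for k in _GRAMMAR_LEARNER_MEAN},
        sd={k: 0.0 for k in _GRAMMAR_LEARNER_MEAN},
        conscious_control=0.0,
    ),
}


def make_participant(
    preset: str | ModelDistribution, rng: np.random.Generator
) -> ParticipantModel:
    dist = PRESETS[preset] if isinstance(preset, str) else preset
    return dist.draw(rng)


def _evidence(model: ParticipantModel, features: dict[str, float]) -> float:
    e = model.weights.get("intercept", 0.0)
    for name, value in features.items():
        e += model.weights.get(name, 0.0) * value
    return e


def simulate_choice(
    model: ParticipantModel,
    features: dict[str, float],
    phase: str,
    rng: np.random.Generator,
) -> tuple[bool, int]:
    """Simulate one trial: returns (chose_grammatical, confidence).

    Inclusion: P(choose grammatical) = logistic(evidence).  Exclusion:
    with probability ``conscious_control`` the knowledge-driven choice
    is reversed.  Confidence = 50 + 50*tanh(gain*|evidence|), rounded.
    """
    if phase not in ("inclusion", "exclusion"):
        raise ValueError(f"unknown phase {phase!r}")
    e = _evidence(model, features)
    p = 1.0 / (1.0 + math.exp(-e))
    chose_grammatical = bool(rng.random() < p)
    if phase == "exclusion" and rng.random() < model.conscious_control:
        chose_grammatical = not chose_grammatical
    confidence = round(50 + 50 * math.tanh(model.confidence_gain * abs(e)))
    return chose_grammatical, max(50, min(100, confidence))


def simulate_participant(
    model: ParticipantModel,
    pairs: list[TestPair],
    features: pd.DataFrame,
    rng: np.random.Generator,
    participant: str,
    group: str,
    variant: str,
) -> pd.DataFrame:
    """Inclusion then exclusion run over all pairs, each phase in an
    independent per-participant random order."""
    rows = []
    for phase in ("inclusion", "exclusion"):
        order = rng.permutation(len(pairs))
        for rank, idx in enumerate(order):
            pair = pairs[int(idx)]
            feats = features.loc[pair.pair_id].to_dict()
            chose, conf = simulate_choice(model, feats, phase, rng)
            u = pair.ungrammatical
            rows.append(
                {
                    "participant": participant,
                    "group": group,
                    "variant": variant,
                    "phase": phase,
                    "trial": rank,
                    "pair_id": pair.pair_id,
                    "chose_grammatical": chose,
                    "confidence": conf,
                    "gram_status": pair.grammatical.status,
                    "ungram_status": u.status,
                    "violated_layer": u.violated_layer,
                    "locality": u.locality,
                }
            )
    return pd.DataFrame(rows)


def simulate_group(
    design: StimulusSet,
    features: pd.DataFrame,
    n_participants: int,
    preset: str | ModelDistribution,
    rng: np.random.Generator,
    group: str = "trained",
    id_prefix: str = "p",
) -> pd.DataFrame:
    """Simulate a participant group on one condition's test pairs.

    Returns a tidy record frame: one row per trial (132 per
    participant -- 66 inclusion followed by 66 exclusion).
    """
    frames = []
    for i in range(n_participants):
        model = make_participant(preset, rng)
        frames.append(
            simulate_participant(
                model,
                list(design.pairs),
                features,
                rng,
                participant=f"{id_prefix}{i:03d}",
                group=group,
                variant=design.variant,
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_category_test(
    model: ParticipantModel,
    lexicon: Lexicon,
    rng: np.random.Generator,
    n_trials: int = 14,
) -> pd.DataFrame:
    """Triadic category test: per trial, two same-class words plus one
    word of another class; the participant is correct (picks the two
    same-class words) with probability ``p_category`` (1/3 = chance).
    """
    classes = [c for c, ws in lexicon.words.items() if len(ws) >= 2]
    if not classes:
        raise ValueError("lexicon needs a class with >= 2 words")
    rows = []
    for t in range(n_trials):
        same = classes[int(rng.integers(len(classes)))]
        others = [c for c in lexicon.words if c != same]
        other = others[int(rng.integers(len(others)))]
        pair = rng.choice(len(lexicon[same]), size=2, replace=False)
        triad = [
            lexicon[same][int(pair[0])],
            lexicon[same][int(pair[1])],
            lexicon[other][int(rng.integers(len(lexicon[other])))],
        ]
        rows.append(
            {
                "trial": t,
                "words": " ".join(triad),
                "target_class": same,
                "correct": bool(rng.random() < model.p_category),
            }
        )
    return pd.DataFrame(rows)
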