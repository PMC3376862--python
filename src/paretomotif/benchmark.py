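"""Synthetic planted-motif benchmark generator and scenario grid runner.

Datasets are built in two steps: i.i.d. background sequences (uniform,
AT-rich or GC-rich composition), then one instance of each motif planted
per sequence at a random non-overlapping position.  Planting overwrites
the background in place, so sequence lengths are unchanged.  Instances
are drawn column-wise from a conservation-controlled profile: the
consensus base has probability 0.91 (high conservation) or 0.70 (low),
the other three bases share the remainder equally (0.03 / 0.10 each).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .core import (
    BASE_INDEX,
    SequenceSet,
    SiteAnnotation,
    ValidationError,
    decode_sequence,
    encode_sequence,
)
from .engine import GAConfig, evolve
from . import metrics

Background = Literal["uniform", "at_rich", "gc_rich"]
Conservation = Literal["high", "low"]

#: base probabilities (A, C, G, T) of each background composition; the
#: rich compositions split the 60% pair total equally between its bases
BACKGROUND_PROBS: dict[str, np.ndarray] = {
    "uniform": np.array([0.25, 0.25, 0.25, 0.25]),
    "at_rich": np.array([0.30, 0.20, 0.20, 0.30]),
    "gc_rich": np.array([0.20, 0.30, 0.30, 0.20]),
}

#: (dominant, other) base probabilities per conservation level
CONSERVATION_PROBS = {"high": (0.91, 0.03), "low": (0.70, 0.10)}
CONSERVATION_DOMINANT = {k: v[0] for k, v in CONSERVATION_PROBS.items()}

_MAX_PLACEMENT_TRIES = 1000


@dataclass(frozen=True)
class PlantedMotif:
    """One motif to embed: its consensus and conservation level."""

    consensus: str
    conservation: Conservation
    label: str = ""

    def __post_init__(self):
        if not 4 <= len(self.consensus) <= 20:
            raise ValidationError(
                f"motif width {len(self.consensus)} outside [4, 20]"
            )
        encode_sequence(self.consensus)  # alphabet check
        if self.conservation not in CONSERVATION_DOMINANT:
            raise ValidationError(f"unknown conservation {self.conservation!r}")

    @property
    def width(self) -> int:
        return len(self.consensus)


@dataclass(frozen=True)
class ScenarioSpec:
    """A full synthetic dataset recipe.

    ``motifs`` may mix explicit consensus strings with ``(width,
    conservation)`` requests; widths are filled with a random consensus
    drawn from the scenario seed.
    """

    n_sequences: int
    seq_length: int
    background: Background = "uniform"
    motifs: tuple[PlantedMotif, ...] = ()
    rng_seed: int = 0

    def __post_init__(self):
        if self.background not in BACKGROUND_PROBS:
            raise ValidationError(f"unknown background {self.background!r}")
        total = sum(m.width for m in self.motifs)
        if total >= self.seq_length:
            raise ValidationError(
                f"total motif width {total} does not fit in {self.seq_length} bp"
            )


@dataclass(frozen=True)
class GroundTruth:
    """Planted-site bookkeeping: one annotation per (sequence, motif)."""

    sites: tuple[SiteAnnotation, ...]
    instances: tuple[str, ...]  # planted strings aligned with ``sites``

    def for_motif(self, label: str) -> list[SiteAnnotation]:
        return [s for s in self.sites if s.name == label]


def random_consensus(width: int, rng: np.random.Generator) -> str:
    """Uniform random consensus string of the given width."""
    return decode_sequence(rng.integers(0, 4, size=width))


def sample_background(n: int, length: int, background: Background,
                      rng: np.random.Generator) -> SequenceSet:
    """n i.i.d. sequences of the given length and base composition."""
    if length < 1:
        raise ValidationError("length must be >= 1")
    probs = BACKGROUND_PROBS.get(background)
    if probs is None:
        raise ValidationError(f"unknown background {background!r}")
    records = []
    for i in range(n):
        arr = rng.choice(4, size=length, p=probs)
        records.append((f"seq_{i + 1}", decode_sequence(arr)))
    return SequenceSet(records)


def conservation_profile(consensus: str, level: Conservation) -> np.ndarray:
    """Per-position base distribution (4 x width) for a planted motif.

    The consensus base gets the dominant probability of its conservation
    level; the other three bases split the remainder equally.
    """
    if level not in CONSERVATION_PROBS:
        raise ValidationError(f"unknown conservation level {level!r}")
    dom, rest = CONSERVATION_PROBS[level]
    w = len(consensus)
    profile = np.full((4, w), rest)
    for j, base in enumerate(consensus):
        b = BASE_INDEX.get(base)
        if b is None:
            raise ValidationError(f"invalid base {base!r} in consensus")
        profile[b, j] = dom
    return profile


def sample_instance(profile: np.ndarray, rng: np.random.Generator) -> str:
    """Draw one base per column from the profile's distributions."""
    w = profile.shape[1]
    out = np.empty(w, dtype=np.uint8)
    for j in range(w):
        out[j] = rng.choice(4, p=profile[:, j])
    return decode_sequence(out)


def plant_motifs(seqs: SequenceSet, spec: ScenarioSpec,
                 rng: np.random.Generator) -> tuple[SequenceSet, GroundTruth]:
    """Overwrite each sequence with one fresh instance of every motif.

    Positions are uniform; placements within one sequence never overlap
    (rejection sampling with a bounded number of retries).
    """
    profiles = [conservation_profile(m.consensus, m.conservation)
                for m in spec.motifs]
    labels = [m.label or f"motif_{k + 1}" for k, m in enumerate(spec.motifs)]
    new_records = []
    annotations: list[SiteAnnotation] = []
    instances: list[str] = []
    for i, (ident, seq) in enumerate(seqs):
        arr = bytearray(seq, "ascii")
        occupied: list[tuple[int, int]] = []
        for k, motif in enumerate(spec.motifs):
            w = motif.width
            hi = len(seq) - w
            for _ in range(_MAX_PLACEMENT_TRIES):
                p = int(rng.integers(0, hi + 1))
                if all(p + w <= s or p >= e for s, e in occupied):
                    break
            else:
                raise ValidationError(
                    f"could not place motif {labels[k]!r} without overlap in "
                    f"sequence {ident!r}"
                )
            occupied.append((p, p + w))
            inst = sample_instance(profiles[k], rng)
            arr[p:p + w] = inst.encode("ascii")
            annotations.append(SiteAnnotation(ident, p, p + w, name=labels[k]))
            instances.append(inst)
        new_records.append((ident, arr.decode("ascii")))
    return (SequenceSet(new_records),
            GroundTruth(tuple(annotations), tuple(instances)))


def generate_scenario(spec: ScenarioSpec,
                      rng: np.random.Generator | None = None,
                      ) -> tuple[SequenceSet, GroundTruth]:
    """Background sampling followed by motif planting, from one seed."""
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    bg = sample_background(spec.n_sequences, spec.seq_length, spec.background, rng)
    return plant_motifs(bg, spec, rng)


def front_site_annotations(front, seqs: SequenceSet) -> dict[str, list[SiteAnnotation]]:
    """Per-front-member predicted sites, keyed by a width-tagged label."""
    out: dict[str, list[SiteAnnotation]] = {}
    for cand, fv, consensus in front:
        label = f"w{cand.width}_{consensus}"
        out[label] = [
            SiteAnnotation(seqs.ids[i], p, p + cand.width, name=label,
                           score=fv.similarity)
            for i, p in enumerate(cand.starts)
        ]
    return out


def evaluate_front(front, seqs: SequenceSet, truth: GroundTruth,
                   spec: ScenarioSpec,
                   min_overlap_fraction: float = 0.5) -> pd.DataFrame:
    """Assign discovered motifs to planted motifs and score each planted one.

    The assignment maximizes total F over the small (planted x discovered)
    matrix, one-to-one; a planted motif with no assigned discovery scores 0.
    Returns one row per planted motif.
    """
    labels = [m.label or f"motif_{k + 1}" for k, m in enumerate(spec.motifs)]
    truth_by_motif = {lab: truth.for_motif(lab) for lab in labels}
    predicted = front_site_annotations(front, seqs)
    pred_labels = list(predicted)
    assignment = metrics.assign_motifs(
        {lab: truth_by_motif[lab] for lab in labels},
        predicted,
        min_overlap_fraction=min_overlap_fraction,
    )
    rows = []
    for k, motif in enumerate(spec.motifs):
        lab = labels[k]
        match = assignment.get(lab)
        if match is None:
            prec = rec = f = 0.0
            disc_w, disc_cons = 0, ""
        else:
            pred_lab, result = match
            prec, rec, f = metrics.f_measures(result.tp, result.fp, result.fn)
            disc_w = int(pred_lab.split("_")[0][1:])
            disc_cons = pred_lab.split("_", 1)[1]
        rows.append({
            "motif": lab,
            "consensus": motif.consensus,
            "conservation": motif.conservation,
            "width": motif.width,
            "discovered_width": disc_w,
            "discovered_consensus": disc_cons,
            "precision": prec,
            "recall": rec,
            "f_score": f,
        })
    return pd.DataFrame(rows)


def run_scenario(spec: ScenarioSpec, ga_config: GAConfig,
                 min_overlap_fraction: float = 0.5) -> pd.DataFrame:
    """Generate one dataset, run the GA, score every planted motif."""
    seqs, truth = generate_scenario(spec)
    front = evolve(seqs, ga_config)
    out = evaluate_front(front, seqs, truth, spec, min_overlap_fraction)
    out.insert(0, "n_sequences", spec.n_sequences)
    out.insert(1, "seq_length", spec.seq_length)
    out.insert(2, "n_motifs", len(spec.motifs))
    return out


def run_recovery(n_sequences: int, seq_length: int,
                 motifs: Sequence[tuple[int, Conservation]],
                 replicates: int = 10, base_seed: int = 1,
                 ga_config: GAConfig | None = None,
                 background: Background = "uniform",
                 min_overlap_fraction: float = 0.5) -> pd.DataFrame:
    """Planted-motif recovery experiment over independently drawn datasets.

    ``motifs`` are ``(width, conservation)`` requests; every replicate draws
    fresh consensus strings, a fresh dataset and a fresh GA seed from
    ``(base_seed, replicate)``, so replicates are independent repetitions of
    the same scenario recipe.  Returns one row per (replicate, planted
    motif) with site-level precision/recall/F.
    """
    if ga_config is None:
        ga_config = GAConfig()
    frames = []
    for rep in range(1, replicates + 1):
        ss = np.random.SeedSequence([base_seed, rep])
        cons_seed, data_seed, ga_seed = (int(x) for x in
                                         ss.generate_state(3) % (2 ** 31))
        rng = np.random.default_rng(cons_seed)
        planted = tuple(
            PlantedMotif(random_consensus(w, rng), level, f"motif_{k + 1}")
            for k, (w, level) in enumerate(motifs)
        )
        spec = ScenarioSpec(n_sequences, seq_length, background, planted,
                            rng_seed=data_seed)
        cfg = GAConfig(**{**ga_config.__dict__, "rng_seed": ga_seed})
        df = run_scenario(spec, cfg, min_overlap_fraction)
        df.insert(0, "replicate", rep)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def run_scenario_grid(specs: Sequence[ScenarioSpec], ga_config: GAConfig,
                      replicates: int = 10,
                      min_overlap_fraction: float = 0.5) -> pd.DataFrame:
    """Run every scenario for several seeded replicates.

    Replicate ``r`` of scenario ``s`` reseeds both the dataset and the GA
    from ``(spec.rng_seed, r)``, so the whole grid is reproducible from
    the scenario seeds alone.  Returns a tidy table with one row per
    (scenario, replicate, planted motif).
    """
    frames = []
    for s_idx, spec in enumerate(specs):
        for r in range(1, replicates + 1):
            ss = np.random.SeedSequence([spec.rng_seed, r])
            data_seed, ga_seed = (int(x) for x in ss.generate_state(2) % (2 ** 31))
            rep_spec = ScenarioSpec(
                spec.n_sequences, spec.seq_length, spec.background,
                spec.motifs, rng_seed=data_seed,
            )
            rep_config = GAConfig(**{**ga_config.__dict__, "rng_seed": ga_seed})
            df = run_scenario(rep_spec, rep_config, min_overlap_fraction)
            df.insert(0, "scenario", s_idx + 1)
            df.insert(1, "replicate", r)
            frames.append(df)
    return pd.concat(frames, ignore_index=True)
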