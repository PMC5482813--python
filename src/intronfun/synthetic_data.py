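"""Synthetic data with the statistical structure the analysis assumes.

Two levels of simulation:

* **Pattern level** (:func:`simulate_patterns` / :func:`simulate_dataset`)
  evolves intron presence/absence down the dated tree under a two-state
  gain/loss process with class-dependent rates: truly functional introns
  have a lower loss rate, an origin biased toward presence at the root, and
  positions biased toward the CDS start; non-functional introns are lost
  faster and sit anywhere along the CDS.  Observed labels are a one-sided
  noisy version of the truth (a functional pattern is annotated with
  probability ``theta11``; a non-functional one never is).
* **Feature level** (:func:`simulate_features`) draws feature vectors from a
  known logistic ground truth — the clean test bed for the classifier and
  the EM estimator.

:func:`simulate_architecture_files` additionally writes the junction TSV /
element BED / ground-truth TSV trio that the extraction pipeline reads, so
the whole workflow can be exercised end to end.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .patterns import (
    MISSING_FRACTION_MAX, Occurrence, UniquePattern,
    LABEL_FUNCTIONAL, LABEL_NON_FUNCTIONAL,
)
from .phylo import Phylogeny, default_tree

__all__ = [
    "ClassParams",
    "SimConfig",
    "simulate_patterns",
    "apply_label_noise",
    "simulate_dataset",
    "simulate_features",
    "simulate_architecture_files",
]

HUMAN = "Homo_sapiens"


@dataclass(frozen=True)
class ClassParams:
    """Gain/loss process and position distribution for one functionality class."""

    gain: float            # events per MY
    loss: float            # events per MY
    root_pi1: float        # P(present at root)
    position_scale: float | None  # mean of the exponential CDS-offset draw; None = uniform

    def transition(self, t: float) -> np.ndarray:
        s = self.gain + self.loss
        if s == 0:
            return np.eye(2)
        e = math.exp(-s * t)
        p1 = self.gain / s
        return np.array([[1 - p1 * (1 - e), p1 * (1 - e)],
                         [(1 - p1) * (1 - e), p1 + (1 - p1) * e]])


@dataclass
class SimConfig:
    """Generative parameters; the defaults define the standard study conditions.

    About 10% of patterns are truly functional and ~20% of those are
    annotated (one-sided label noise), matching the composition a curated
    intron-function data set exhibits.  Functional introns lose at a
    fraction of the background loss rate, tend to be present at the root,
    and sit near the CDS start; non-functional introns are lost an order of
    magnitude faster and are positioned uniformly.
    """

    tree: Phylogeny = None
    n_patterns: int = 2000
    pi_f: float = 0.10
    theta11: float = 0.2
    functional: ClassParams = field(default_factory=lambda: ClassParams(
        gain=6e-4, loss=2e-4, root_pi1=0.8, position_scale=300.0))
    nonfunctional: ClassParams = field(default_factory=lambda: ClassParams(
        gain=6e-4, loss=2e-3, root_pi1=0.5, position_scale=None))
    missing_prob: float = 0.2          # per non-human species
    cds_log_mean: float = math.log(1500.0)
    cds_log_sigma: float = 0.4
    patterns_per_set: int = 5          # architecture-level only
    logistic_w: tuple[float, ...] = (3.0, 3.0)   # feature-level ground truth
    logistic_w0: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tree is None:
            self.tree = default_tree()
        for p in (self.pi_f, self.theta11, self.missing_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_patterns < 1:
            raise ValueError("n_patterns must be >= 1")


def _evolve(tree: Phylogeny, params: ClassParams, rng: np.random.Generator) -> np.ndarray:
    """One draw of leaf presence/absence states (ordered as tree.taxa)."""
    states = np.zeros(tree.n_nodes, dtype=np.int8)
    root = tree.root
    states[root] = rng.random() < params.root_pi1
    for node in reversed(range(tree.n_nodes)):  # top-down
        for child in tree.children[node]:
            p = params.transition(float(tree.edge_length[child]))[states[node]]
            states[child] = rng.random() < p[1]
    return states[tree.leaf_nodes]


def _draw_position(params: ClassParams, cds_length: int, rng: np.random.Generator) -> int:
    if params.position_scale is None:
        return int(rng.integers(1, cds_length + 1))
    pos = 1 + int(rng.exponential(params.position_scale))
    return min(pos, cds_length)


def _draw_cds_length(config: SimConfig, rng: np.random.Generator) -> int:
    length = int(round(rng.lognormal(config.cds_log_mean, config.cds_log_sigma)))
    return int(np.clip(length, 300, 20000))


def _simulate_occurrence_values(config: SimConfig, rng: np.random.Generator,
                                max_attempts: int = 200) -> tuple[np.ndarray, int]:
    """Leaf values {0,1,2} with human = 1 and missing fraction below the filter.

    Returns (values in tree leaf order, class index 1=functional).
    Rejection-samples the conditioning; raises after ``max_attempts``.
    """
    tree = config.tree
    human_idx = tree.taxa.index(HUMAN)
    # class membership is drawn once so the functional fraction stays pi_f;
    # only the evolutionary draw is rejection-sampled on human presence
    is_functional = rng.random() < config.pi_f
    params = config.functional if is_functional else config.nonfunctional
    for _ in range(max_attempts):
        states = _evolve(tree, params, rng)
        if states[human_idx] != 1:
            continue
        values = states.astype(np.int8)
        miss = rng.random(tree.n_leaves) < config.missing_prob
        miss[human_idx] = False
        values[miss] = 2
        if (values == 2).sum() / tree.n_leaves >= MISSING_FRACTION_MAX:
            continue
        return values, int(is_functional)
    raise RuntimeError(
        "could not draw a pattern with a human intron; the configured rates "
        "produce (nearly) all-absent patterns"
    )


def simulate_patterns(config: SimConfig) -> tuple[list[UniquePattern], np.ndarray]:
    """Draw patterns, collapse identical vectors, return (patterns, true y).

    The true label of a collapsed unique pattern is the majority class of
    the draws that produced it (ties count as functional).  Labels on the
    returned patterns are placeholders (non-functional) until observed
    labels are attached via :func:`apply_label_noise` /
    :func:`label_patterns`.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    tree = config.tree
    draws: dict[tuple, dict] = {}
    order: list[tuple] = []
    for i in range(config.n_patterns):
        values, y = _simulate_occurrence_values(config, rng)
        cds = _draw_cds_length(config, rng)
        params = config.functional if y else config.nonfunctional
        pos = _draw_position(params, cds, rng)
        occ = Occurrence(set_id=f"sim{i:06d}", column=pos - 1,
                         position=pos, cds_length=cds, tags=())
        key = tuple(int(v) for v in values)
        if key not in draws:
            draws[key] = {"occurrences": [], "y_votes": []}
            order.append(key)
        draws[key]["occurrences"].append(occ)
        draws[key]["y_votes"].append(y)

    patterns, y_true = [], []
    for key in order:
        votes = draws[key]["y_votes"]
        y = int(np.mean(votes) >= 0.5)
        patterns.append(UniquePattern(
            values=np.asarray(key, dtype=np.int8),
            species=list(tree.taxa),
            occurrences=draws[key]["occurrences"],
            label=LABEL_NON_FUNCTIONAL,
        ))
        y_true.append(y)
    return patterns, np.asarray(y_true, dtype=int)


def apply_label_noise(y: np.ndarray, theta11: float, seed: int = 0) -> np.ndarray:
    """One-sided noise: z = Bernoulli(theta11) when y = 1, z = 0 when y = 0."""
    if not 0.0 <= theta11 <= 1.0:
        raise ValueError("theta11 must lie in [0, 1]")
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(seed)
    return ((y == 1) & (rng.random(y.shape) < theta11)).astype(int)


def label_patterns(patterns: list[UniquePattern], z: np.ndarray,
                   tag: str = "TFBS") -> None:
    """Attach observed labels in place: z=1 patterns get tagged occurrences."""
    for pattern, zi in zip(patterns, z):
        if zi:
            pattern.label = LABEL_FUNCTIONAL
            pattern.occurrences = [replace(o, tags=(tag,)) for o in pattern.occurrences]
            pattern.sublabels = {tag: LABEL_FUNCTIONAL}
        else:
            pattern.label = LABEL_NON_FUNCTIONAL
            pattern.sublabels = {}


def simulate_dataset(config: SimConfig) -> tuple[list[UniquePattern], np.ndarray, np.ndarray]:
    """Patterns with observed labels attached; returns (patterns, y, z)."""
    patterns, y = simulate_patterns(config)
    z = apply_label_noise(y, config.theta11, seed=config.seed + 1)
    label_patterns(patterns, z)
    return patterns, y, z


def simulate_features(config: SimConfig, n: int | None = None
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Feature-level draw from the logistic ground truth.

    x ~ N(0, I) with dim = len(config.logistic_w); y ~ Bernoulli(p(y=1|x))
    under the configured (w, w0); z from one-sided noise.  Returns
    (x, y, z, p).
    """
    n = n or config.n_patterns
    rng = np.random.default_rng(config.seed)
    w = np.asarray(config.logistic_w, float)
    x = rng.standard_normal((n, w.size))
    p = 1.0 / (1.0 + np.exp(-(x @ w - config.logistic_w0)))
    y = (rng.random(n) < p).astype(int)
    z = ((y == 1) & (rng.random(n) < config.theta11)).astype(int)
    return x, y, z, p


def simulate_architecture_files(config: SimConfig, out_dir) -> dict:
    """Write junction TSV, element BED and ground-truth TSV for the pipeline.

    Occurrences are grouped into ortholog sets of ``patterns_per_set``
    columns; a species missing from a set lacks a row in the junction TSV
    (all-missing in the ternary encoding).  Element tags are drawn per
    occurrence: a truly functional intron is annotated with probability
    ``theta11``.  Returns the paths written.
    """
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    tree = config.tree
    human_idx = tree.taxa.index(HUMAN)
    n_sets = math.ceil(config.n_patterns / config.patterns_per_set)

    junction_rows, bed_rows, truth_rows = [], [], []
    remaining = config.n_patterns
    for s in range(n_sets):
        set_id = f"set{s:05d}"
        k = min(config.patterns_per_set, remaining)
        remaining -= k
        miss = rng.random(tree.n_leaves) < config.missing_prob
        miss[human_idx] = False
        cds = _draw_cds_length(config, rng)
        positions: set[int] = set()
        columns = []
        for _ in range(k):
            # class first, so the functional fraction stays pi_f; only the
            # evolutionary draw is conditioned on human presence
            is_functional = rng.random() < config.pi_f
            params = config.functional if is_functional else config.nonfunctional
            for _ in range(200):
                states = _evolve(tree, params, rng)
                if states[human_idx] == 1:
                    break
            else:
                warnings.warn("architecture simulation could not place a human intron")
                continue
            for _ in range(200):
                pos = _draw_position(params, cds, rng)
                if pos not in positions:
                    break
            positions.add(pos)
            tagged = bool(is_functional and rng.random() < config.theta11)
            columns.append((pos, states, int(is_functional), tagged))
        for species_i, name in enumerate(tree.taxa):
            if miss[species_i]:
                continue
            juncs = sorted(pos for pos, states, _, _ in columns if states[species_i] == 1)
            junction_rows.append(
                f"{set_id}\t{name}\t{cds}\t{','.join(map(str, juncs))}"
            )
        for pos, states, y, tagged in columns:
            if tagged:
                bed_rows.append(f"{set_id}\t{pos - 1}\t{pos}\tTFBS")
            truth_rows.append(f"{set_id}\t{pos}\t{y}")

    paths = {
        "junctions": out / "junctions.tsv",
        "elements": out / "elements.bed",
        "truth": out / "truth.tsv",
    }
    paths["junctions"].write_text(
        "# set_id\tspecies\tcds_length\tjunctions\n" + "\n".join(junction_rows) + "\n")
    paths["elements"].write_text("\n".join(bed_rows) + ("\n" if bed_rows else ""))
    paths["truth"].write_text(
        "# set_id\tjunction_position\ty_true\n" + "\n".join(truth_rows) + "\n")
    return {k: str(v) for k, v in paths.items()}
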