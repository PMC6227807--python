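"""Seeded generator of single-cell expression data with regulatory-substate structure.

A population is a mixture of discrete network substates: each cell first
draws a substate by mixture weight, then each gene fires on/off with that
substate's probability, then detection-limit dropout independently silences
"on" calls. Expression levels for "on" calls are drawn from a log-normal
distribution; their exact shape is irrelevant to every entropy result
(binarization erases it) and exists only to exercise the Ct transforms.

Mixtures of well-separated substates produce the signature the analysis
looks for: high per-gene entropy together with strong pairwise correlation.
``true_population_entropy`` returns the exact mixture-implied entropies so
sampled estimates can be checked against closed-form oracles.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .entropy import _plugin_entropy
from .exceptions import ConfigurationError
from .io import ExpressionMatrix, GUO_BACKGROUND_CT, PINA_DETECTION_LIMIT

__all__ = [
    "SubstateSpec",
    "StageSpec",
    "ScenarioSpec",
    "sample_population",
    "generate_scenario",
    "true_population_entropy",
    "default_commitment_scenario",
    "to_ct_convention",
    "load_scenario",
]

_WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class SubstateSpec:
    """One discrete network configuration inside a population.

    ``on_probability`` gives each gene's firing probability in this substate
    (typically near 0 or 1); ``weight`` is its share of the population
    mixture. ``level_log_mean``/``level_log_sd`` parameterize the log-normal
    level distribution for "on" calls.
    """

    on_probability: tuple[float, ...]
    weight: float
    level_log_mean: float = 1.5
    level_log_sd: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "on_probability", tuple(float(q) for q in self.on_probability)
        )
        if any(not (0.0 <= q <= 1.0) for q in self.on_probability):
            raise ConfigurationError("on probabilities must lie in [0, 1]")
        if not (0.0 <= self.weight <= 1.0):
            raise ConfigurationError(f"weight {self.weight} must lie in [0, 1]")


@dataclass(frozen=True)
class StageSpec:
    """A labelled population: a substate mixture plus a dropout rate."""

    label: str
    n_cells: int
    substates: tuple[SubstateSpec, ...]
    dropout: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "substates", tuple(self.substates))
        if self.n_cells < 2:
            raise ConfigurationError(f"stage {self.label!r}: n_cells must be >= 2")
        if not (0.0 <= self.dropout < 1.0):
            raise ConfigurationError(f"stage {self.label!r}: dropout must be in [0, 1)")
        if not self.substates:
            raise ConfigurationError(f"stage {self.label!r}: needs >= 1 substate")
        total = sum(s.weight for s in self.substates)
        if abs(total - 1.0) > _WEIGHT_TOL:
            raise ConfigurationError(
                f"stage {self.label!r}: substate weights sum to {total}, not 1"
            )
        n_genes = len(self.substates[0].on_probability)
        if any(len(s.on_probability) != n_genes for s in self.substates):
            raise ConfigurationError(
                f"stage {self.label!r}: substates disagree on gene count"
            )

    @property
    def n_genes(self) -> int:
        return len(self.substates[0].on_probability)


@dataclass(frozen=True)
class ScenarioSpec:
    """An ordered series of stages forming a differentiation path or tree.

    ``edges`` (parent label, child label) define a tree; when empty the
    stages form a linear path in listed order. ``convention`` selects the
    output value space: direct expression, Guo-style raw Ct, or Pina-style
    delta Ct.
    """

    stages: tuple[StageSpec, ...]
    seed: int = 0
    convention: str = "none"
    edges: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "stages", tuple(self.stages))
        object.__setattr__(self, "edges", tuple(tuple(e) for e in self.edges))
        labels = [s.label for s in self.stages]
        if len(set(labels)) != len(labels):
            raise ConfigurationError(f"duplicate stage labels in {labels}")
        if self.convention not in ("none", "guo", "pina"):
            raise ConfigurationError(f"unknown convention {self.convention!r}")
        known = set(labels)
        for a, b in self.edges:
            if a not in known or b not in known:
                raise ConfigurationError(f"edge ({a!r}, {b!r}) names an unknown stage")

    @property
    def ordering(self) -> list[str] | list[tuple[str, str]]:
        if self.edges:
            return list(self.edges)
        return [s.label for s in self.stages]


def sample_population(
    spec: StageSpec, seed: int | np.random.Generator
) -> ExpressionMatrix:
    """Draw one population of cells from a substate mixture.

    Per cell: substate by weight, then per-gene Bernoulli calls, then
    independent dropout of "on" calls, then positive log-normal levels where
    the final call is on. Byte-identical for identical seeds.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n, g = spec.n_cells, spec.n_genes
    weights = np.array([s.weight for s in spec.substates])
    q = np.array([s.on_probability for s in spec.substates])  # (K, g)
    ks = rng.choice(len(spec.substates), size=n, p=weights / weights.sum())
    calls = (rng.random((n, g)) < q[ks]).astype(np.int8)
    if spec.dropout > 0:
        calls &= (rng.random((n, g)) >= spec.dropout).astype(np.int8)
    mu = np.array([s.level_log_mean for s in spec.substates])[ks]
    sd = np.array([s.level_log_sd for s in spec.substates])[ks]
    levels = rng.lognormal(mean=mu[:, None], sigma=sd[:, None], size=(n, g))
    values = np.where(calls == 1, levels, 0.0)
    return ExpressionMatrix(
        values=values,
        cell_ids=[f"{spec.label}_c{i}" for i in range(n)],
        gene_ids=[f"g{j}" for j in range(g)],
        population=[spec.label] * n,
    )


def generate_scenario(scenario: ScenarioSpec) -> ExpressionMatrix:
    """Sample every stage and concatenate into one labelled matrix."""
    rng = np.random.default_rng(scenario.seed)
    parts = [sample_population(stage, rng) for stage in scenario.stages]
    genes = parts[0].gene_ids
    for p in parts[1:]:
        if p.gene_ids != genes:
            raise ConfigurationError("stages disagree on gene panel")
    return ExpressionMatrix(
        values=np.vstack([p.values for p in parts]),
        cell_ids=[c for p in parts for c in p.cell_ids],
        gene_ids=genes,
        population=[lab for p in parts for lab in p.population],
    )


def _mixture_on_probability(spec: StageSpec) -> np.ndarray:
    """Exact per-gene P(on) after mixing substates and applying dropout."""
    weights = np.array([s.weight for s in spec.substates])
    q = np.array([s.on_probability for s in spec.substates]) * (1.0 - spec.dropout)
    return weights @ q


def true_population_entropy(spec: StageSpec) -> tuple[float, float]:
    """Exact (marginal bits, normalized pairwise-joint bits) implied by a spec.

    Marginal: mean over genes of the binary entropy of the mixture-implied
    on-probability. Joint: mean over unordered gene pairs of half the joint
    entropy, computed by total probability over substates (genes are
    conditionally independent given the substate, not marginally).
    """
    weights = np.array([s.weight for s in spec.substates])
    q = np.array([s.on_probability for s in spec.substates]) * (1.0 - spec.dropout)
    p_on = weights @ q
    marginal = float(
        np.mean(_plugin_entropy(np.stack([1.0 - p_on, p_on], axis=-1)))
    )
    g = spec.n_genes
    if g < 2:
        return marginal, 0.0
    total = 0.0
    pairs = list(itertools.combinations(range(g), 2))
    for a, b in pairs:
        p11 = float(weights @ (q[:, a] * q[:, b]))
        p10 = float(weights @ (q[:, a] * (1.0 - q[:, b])))
        p01 = float(weights @ ((1.0 - q[:, a]) * q[:, b]))
        p00 = 1.0 - p11 - p10 - p01
        total += float(_plugin_entropy(np.array([p00, p01, p10, p11]))) / 2.0
    return marginal, total / len(pairs)


def default_commitment_scenario(
    n_cells: int = 100,
    n_genes: int = 20,
    seed: int = 0,
    dropout: float = 0.05,
    convention: str = "none",
) -> ScenarioSpec:
    """Three-stage low -> high -> low entropy series with a two-substate middle.

    The precursor and differentiated stages are single near-deterministic
    substates; the commitment stage mixes two complementary substates
    equally, which drives every gene's on-fraction toward 1/2 and the mean
    marginal entropy toward 1 bit while keeping gene pairs strongly
    correlated.
    """
    half = n_genes // 2
    hi, lo = 0.95, 0.05
    precursor = SubstateSpec(
        on_probability=(0.9,) * half + (0.1,) * (n_genes - half), weight=1.0
    )
    committed_a = SubstateSpec(
        on_probability=(hi,) * half + (lo,) * (n_genes - half), weight=0.5
    )
    committed_b = SubstateSpec(
        on_probability=(lo,) * half + (hi,) * (n_genes - half), weight=0.5
    )
    differentiated = SubstateSpec(
        on_probability=(hi,) * half + (lo,) * (n_genes - half), weight=1.0
    )
    stages = (
        StageSpec("precursor", n_cells, (precursor,), dropout=dropout),
        StageSpec("commitment", n_cells, (committed_a, committed_b), dropout=dropout),
        StageSpec("differentiated", n_cells, (differentiated,), dropout=dropout),
    )
    return ScenarioSpec(stages=stages, seed=seed, convention=convention)


def to_ct_convention(m: ExpressionMatrix, convention: str) -> pd.DataFrame:
    """Re-express a matrix in a qPCR value space that the io transforms invert.

    ``guo``: raw Ct = 28 - expression (off calls emit exactly 28);
    ``pina``: delta Ct = 30 - expression/ln 2 (off calls emit exactly 30);
    ``none``: expression values unchanged.
    """
    if convention == "none":
        values = m.values
    elif convention == "guo":
        values = np.where(m.values > 0, GUO_BACKGROUND_CT - m.values, GUO_BACKGROUND_CT)
    elif convention == "pina":
        values = np.where(
            m.values > 0,
            PINA_DETECTION_LIMIT - m.values / np.log(2.0),
            PINA_DETECTION_LIMIT,
        )
    else:
        raise ConfigurationError(f"unknown convention {convention!r}")
    df = pd.DataFrame(values, index=m.cell_ids, columns=m.gene_ids)
    df.insert(0, "population", m.population)
    df.index.name = "cell_id"
    return df


def load_scenario(path) -> ScenarioSpec:
    """Load a :class:`ScenarioSpec` from a YAML file.

    Expected layout::

        seed: 7
        convention: none
        edges: [[P, C], [C, D]]        # optional; omit for a linear path
        stages:
          - label: P
            n_cells: 100
            dropout: 0.05
            substates:
              - weight: 1.0
                on_probability: [0.9, 0.9, 0.1, 0.1]
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "stages" not in raw:
        raise ConfigurationError(f"{path}: scenario file must define 'stages'")
    stages = []
    for s in raw["stages"]:
        try:
            substates = tuple(
                SubstateSpec(
                    on_probability=tuple(sub["on_probability"]),
                    weight=float(sub["weight"]),
                    level_log_mean=float(sub.get("level_log_mean", 1.5)),
                    level_log_sd=float(sub.get("level_log_sd", 0.5)),
                )
                for sub in s["substates"]
            )
            stages.append(
                StageSpec(
                    label=str(s["label"]),
                    n_cells=int(s["n_cells"]),
                    substates=substates,
                    dropout=float(s.get("dropout", 0.0)),
                )
            )
        except KeyError as exc:
            raise ConfigurationError(f"{path}: stage missing key {exc}") from exc
    return ScenarioSpec(
        stages=tuple(stages),
        seed=int(raw.get("seed", 0)),
        convention=str(raw.get("convention", "none")),
        edges=tuple((str(a), str(b)) for a, b in raw.get("edges", [])),
    )
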