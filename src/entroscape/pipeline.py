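"""Per-population entropy profiles, per-gene tables and trajectory peak detection.

Population aggregates are unweighted means: the marginal profile averages
per-gene binary entropies over genes, the joint profile averages normalized
pairwise joint entropies (H12 / 2) over all unordered gene pairs. Standard
errors jackknife over cells — deleting a cell shifts exactly one count per
gene (or per pair state), so every leave-one-out aggregate is assembled from
a small table of per-gene (per-pair) deleted-count entropies instead of
re-running the estimator n times. The generic loop in
:mod:`entroscape.resampling` serves as the independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .entropy import ESTIMATORS, EntropyEstimate
from .exceptions import ConfigurationError, InputError
from .io import BinaryMatrix, binarize, read_expression_table
from .resampling import jackknife_se_from_loo

__all__ = [
    "PopulationEntropyProfile",
    "Trajectory",
    "RunConfig",
    "population_marginal_entropy",
    "population_joint_entropy",
    "gene_entropy_table",
    "compute_profile",
    "entropy_trajectory",
    "read_ordering",
    "run_analysis",
]


def _get_estimator(estimator: str) -> Callable:
    try:
        return ESTIMATORS[estimator]
    except KeyError:
        raise ConfigurationError(
            f"unknown estimator {estimator!r}; use one of {sorted(ESTIMATORS)}"
        ) from None


def _population_calls(b: BinaryMatrix, population: str, min_cells: int = 2) -> np.ndarray:
    calls = b.subset(population)
    if calls.shape[0] < min_cells:
        raise InputError(
            f"population {population!r} has {calls.shape[0]} cells; "
            f"need >= {min_cells} for a jackknife"
        )
    return calls


def _marginal_loo(calls: np.ndarray, fn: Callable) -> tuple[float, np.ndarray]:
    """Full-sample mean per-gene entropy and its n leave-one-out values."""
    n, g = calls.shape
    k_on = calls.sum(axis=0, dtype=np.int64)
    counts = np.stack([n - k_on, k_on], axis=-1)
    full = float(np.mean(fn(counts)))
    # entropy of each gene with one on-call (off-call) deleted; a clipped
    # negative count only occurs where the corresponding indicator is 0
    e_del_on = fn(np.maximum(np.stack([n - k_on, k_on - 1], axis=-1), 0))
    e_del_off = fn(np.maximum(np.stack([n - k_on - 1, k_on], axis=-1), 0))
    on = calls.astype(float)
    loo = (on @ e_del_on + (1.0 - on) @ e_del_off) / g
    return full, loo


def _pair_state_indicators(calls: np.ndarray) -> tuple[np.ndarray, ...]:
    g = calls.shape[1]
    ai, bi = np.triu_indices(g, k=1)
    a = calls[:, ai].astype(float)
    b = calls[:, bi].astype(float)
    return (1 - a) * (1 - b), (1 - a) * b, a * (1 - b), a * b  # states 00,01,10,11


def _joint_loo(calls: np.ndarray, fn: Callable) -> tuple[float, np.ndarray]:
    """Full-sample mean normalized pair entropy and its leave-one-out values."""
    n = calls.shape[0]
    indicators = _pair_state_indicators(calls)
    counts = np.stack([ind.sum(axis=0) for ind in indicators], axis=-1)  # (P, 4)
    full = float(np.mean(fn(counts) / 2.0))
    n_pairs = counts.shape[0]
    loo = np.zeros(n, dtype=float)
    eye = np.eye(4)
    for s, ind in enumerate(indicators):
        deleted = np.maximum(counts - eye[s], 0)
        loo += ind @ (fn(deleted) / 2.0)
    return full, loo / n_pairs


def population_marginal_entropy(
    b: BinaryMatrix, population: str, estimator: str = "ml"
) -> EntropyEstimate:
    """Mean over genes of per-gene binary entropy, with jackknife-over-cells SE.

    Genes with zero variance contribute entropy 0 and are not excluded, so
    populations with different silent-gene counts remain comparable.
    """
    fn = _get_estimator(estimator)
    calls = _population_calls(b, population)
    full, loo = _marginal_loo(calls, fn)
    return EntropyEstimate(
        value=full,
        estimator=estimator,
        se=jackknife_se_from_loo(loo),
        normalized=True,
        n=calls.shape[0],
    )


def population_joint_entropy(
    b: BinaryMatrix, population: str, estimator: str = "ml"
) -> EntropyEstimate:
    """Mean over unordered gene pairs of H12/2, with jackknife-over-cells SE."""
    fn = _get_estimator(estimator)
    calls = _population_calls(b, population)
    if calls.shape[1] < 2:
        raise InputError("joint entropy needs at least two genes")
    full, loo = _joint_loo(calls, fn)
    return EntropyEstimate(
        value=full,
        estimator=estimator,
        se=jackknife_se_from_loo(loo),
        normalized=True,
        n=calls.shape[0],
    )


def gene_entropy_table(b: BinaryMatrix, estimator: str = "ml") -> pd.DataFrame:
    """Per-(gene, population) entropy, jackknife SE, on-fraction and cell count.

    The on-fraction disambiguates zero entropy: a gene silent everywhere and
    a gene expressed by every cell both score 0 bits but sit at opposite
    ends of ``p1``.
    """
    fn = _get_estimator(estimator)
    rows = []
    for pop in b.populations:
        calls = _population_calls(b, pop)
        n = calls.shape[0]
        k_on = calls.sum(axis=0, dtype=np.int64)
        counts = np.stack([n - k_on, k_on], axis=-1)
        h = np.atleast_1d(fn(counts))
        e_del_on = fn(np.maximum(np.stack([n - k_on, k_on - 1], axis=-1), 0))
        e_del_off = fn(np.maximum(np.stack([n - k_on - 1, k_on], axis=-1), 0))
        on = calls.astype(float)
        for j, gene in enumerate(b.gene_ids):
            loo = np.where(on[:, j] == 1, e_del_on[j], e_del_off[j])
            rows.append(
                {
                    "gene": gene,
                    "population": pop,
                    "entropy": float(h[j]),
                    "se": jackknife_se_from_loo(loo),
                    "p1": float(k_on[j]) / n,
                    "n_cells": n,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class PopulationEntropyProfile:
    """Per-population marginal and pairwise-joint entropy aggregates.

    ``table`` is indexed by population label with columns
    ``marginal_entropy``, ``marginal_se``, ``joint_entropy``, ``joint_se``,
    ``n_cells``, ``n_genes``.
    """

    table: pd.DataFrame
    estimator: str = "ml"

    @property
    def populations(self) -> list[str]:
        return list(self.table.index)

    def marginal(self, population: str) -> float:
        return float(self.table.loc[population, "marginal_entropy"])

    def marginal_se(self, population: str) -> float:
        return float(self.table.loc[population, "marginal_se"])


def compute_profile(b: BinaryMatrix, estimator: str = "ml") -> PopulationEntropyProfile:
    """Marginal and joint aggregates for every population in the matrix."""
    records = {}
    for pop in b.populations:
        marg = population_marginal_entropy(b, pop, estimator)
        joint = population_joint_entropy(b, pop, estimator)
        records[pop] = {
            "marginal_entropy": marg.value,
            "marginal_se": marg.se,
            "joint_entropy": joint.value,
            "joint_se": joint.se,
            "n_cells": marg.n,
            "n_genes": b.n_genes,
        }
    table = pd.DataFrame.from_dict(records, orient="index")
    table.index.name = "population"
    return PopulationEntropyProfile(table=table, estimator=estimator)


@dataclass
class Trajectory:
    """Entropy deltas along a user-supplied differentiation ordering.

    ``edges`` are (parent, child) steps; ``deltas`` and ``significant`` are
    parallel to ``edges``. ``peaks`` lists populations whose entropy exceeds
    their predecessor's and every descendant's.
    """

    labels: list[str]
    edges: list[tuple[str, str]]
    deltas: list[float]
    significant: list[bool]
    peaks: list[str]
    value: str = "marginal_entropy"
    z: float = 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parent": [e[0] for e in self.edges],
                "child": [e[1] for e in self.edges],
                "delta": self.deltas,
                "significant": self.significant,
            }
        )


def _edges_from_ordering(
    ordering: Sequence[str] | Sequence[tuple[str, str]],
) -> tuple[list[str], list[tuple[str, str]]]:
    """Normalize a linear path or edge list into (labels, edges); reject cycles."""
    items = list(ordering)
    if not items:
        raise InputError("ordering is empty")
    if isinstance(items[0], str):
        labels = [str(x) for x in items]
        if len(set(labels)) != len(labels):
            raise InputError(f"ordering repeats a label: {labels}")
        return labels, list(zip(labels[:-1], labels[1:]))
    edges = [(str(a), str(b)) for a, b in items]
    labels = list(dict.fromkeys([x for e in edges for x in e]))
    parent: dict[str, str] = {}
    for a, b in edges:
        if b in parent:
            raise InputError(f"label {b!r} has two parents; ordering must be a tree")
        parent[b] = a
    # walk to the root from every node; revisiting a node mid-walk is a cycle
    for node in labels:
        seen = set()
        cur = node
        while cur in parent:
            if cur in seen:
                raise InputError(f"ordering contains a cycle through {cur!r}")
            seen.add(cur)
            cur = parent[cur]
    return labels, edges


def entropy_trajectory(
    profile: PopulationEntropyProfile,
    ordering: Sequence[str] | Sequence[tuple[str, str]],
    value: str = "marginal_entropy",
    z: float = 2.0,
) -> Trajectory:
    """Per-edge entropy deltas, significance flags, and peak populations.

    A delta is flagged significant when it exceeds ``z`` combined jackknife
    standard errors (two-sided). A peak is a population strictly above its
    predecessor (or a root) and strictly above every descendant along its
    paths.
    """
    if value not in ("marginal_entropy", "joint_entropy"):
        raise ConfigurationError(f"unknown profile value {value!r}")
    labels, edges = _edges_from_ordering(ordering)
    missing = [x for x in labels if x not in profile.table.index]
    if missing:
        raise InputError(f"ordering labels missing from profile: {missing}")
    se_col = value.replace("_entropy", "_se")
    vals = {x: float(profile.table.loc[x, value]) for x in labels}
    ses = {x: float(profile.table.loc[x, se_col]) for x in labels}

    deltas, significant = [], []
    for a, b in edges:
        d = vals[b] - vals[a]
        combined = float(np.hypot(ses[a], ses[b]))
        deltas.append(d)
        significant.append(bool(abs(d) > z * combined))

    children: dict[str, list[str]] = {x: [] for x in labels}
    has_parent = set()
    for a, b in edges:
        children[a].append(b)
        has_parent.add(b)
    parent_of = {b: a for a, b in edges}

    def descendants(node: str):
        stack = list(children[node])
        while stack:
            x = stack.pop()
            yield x
            stack.extend(children[x])

    peaks = []
    for node in labels:
        above_parent = node not in has_parent or vals[node] > vals[parent_of[node]]
        above_descendants = all(vals[node] > vals[d] for d in descendants(node))
        if above_parent and above_descendants:
            peaks.append(node)
    return Trajectory(
        labels=labels,
        edges=edges,
        deltas=deltas,
        significant=significant,
        peaks=peaks,
        value=value,
        z=z,
    )


def read_ordering(path) -> list[str] | list[tuple[str, str]]:
    """Read an ordering file: one label per line (path) or two columns (tree edges)."""
    lines = [
        ln.strip()
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise InputError(f"{path}: ordering file is empty")
    rows = [ln.replace(",", " ").split() for ln in lines]
    widths = {len(r) for r in rows}
    if widths == {1}:
        return [r[0] for r in rows]
    if widths == {2}:
        return [(r[0], r[1]) for r in rows]
    raise InputError(
        f"{path}: ordering file must have one column (path) or two (edges)"
    )


@dataclass
class RunConfig:
    """Everything a full analysis run needs; fully determines its outputs."""

    input: str
    outdir: str
    dialect: str = "csv"
    transform: str = "none"
    label_column: str = "population"
    estimator: str = "ml"
    ordering: str | None = None  # path to an ordering file
    seed: int = 0
    z: float = 2.0

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigurationError(f"{path}: unknown config keys {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigurationError(f"{path}: {exc}") from exc


def _header(config: RunConfig) -> str:
    fields = ", ".join(
        f"{k}={getattr(config, k)}" for k in config.__dataclass_fields__
    )
    return f"# entroscape v{__version__}\n# {fields}\n"


def _write_table(df: pd.DataFrame, path: Path, config: RunConfig, index: bool) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", float_format="%.10g", index=index)


def _pairwise_joint_matrix(b: BinaryMatrix, population: str, estimator: str) -> pd.DataFrame:
    """Symmetric gene x gene matrix of normalized pairwise joint entropies."""
    fn = _get_estimator(estimator)
    calls = _population_calls(b, population)
    indicators = _pair_state_indicators(calls)
    counts = np.stack([ind.sum(axis=0) for ind in indicators], axis=-1)
    h = np.atleast_1d(fn(counts)) / 2.0
    g = calls.shape[1]
    mat = np.zeros((g, g))
    ai, bi = np.triu_indices(g, k=1)
    mat[ai, bi] = h
    mat[bi, ai] = h
    return pd.DataFrame(mat, index=b.gene_ids, columns=b.gene_ids)



def _stage(name: str, exc: Exception) -> Exception:
    """Attach the failing stage name, preserving our error types."""
    if isinstance(exc, (InputError, ConfigurationError)):
        return type(exc)(f"[stage: {name}] {exc}")
    return InputError(f"[stage: {name}] {type(exc).__name__}: {exc}")

def run_analysis(config: RunConfig) -> dict[str, Path]:
    """Run the full analysis and write all report tables.

    Outputs under ``config.outdir``: ``population_profile.tsv``,
    ``gene_entropies.tsv``, one ``joint_entropy_<population>.tsv`` matrix per
    population, and ``trajectory.tsv`` when an ordering is given. Every file
    carries a commented header recording version and parameters; identical
    configs produce byte-identical outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        matrix = read_expression_table(
            config.input,
            dialect=config.dialect,
            label_column=config.label_column,
            transform=config.transform,
        )
    except Exception as exc:
        raise _stage("read", exc) from exc
    b = binarize(matrix)

    written: dict[str, Path] = {}
    try:
        profile = compute_profile(b, estimator=config.estimator)
    except Exception as exc:
        raise _stage("profile", exc) from exc
    path = outdir / "population_profile.tsv"
    _write_table(profile.table, path, config, index=True)
    written["profile"] = path

    try:
        genes = gene_entropy_table(b, estimator=config.estimator)
    except Exception as exc:
        raise _stage("gene_table", exc) from exc
    path = outdir / "gene_entropies.tsv"
    _write_table(genes, path, config, index=False)
    written["gene_entropies"] = path

    for pop in b.populations:
        mat = _pairwise_joint_matrix(b, pop, config.estimator)
        path = outdir / f"joint_entropy_{pop}.tsv"
        _write_table(mat, path, config, index=True)
        written[f"joint_matrix:{pop}"] = path

    if config.ordering is not None:
        try:
            ordering = read_ordering(config.ordering)
            traj = entropy_trajectory(profile, ordering, z=config.z)
        except Exception as exc:
            raise _stage("trajectory", exc) from exc
        path = outdir / "trajectory.tsv"
        frame = traj.to_frame()
        with open(path, "w") as fh:
            fh.write(_header(config))
            fh.write(f"# peaks: {','.join(traj.peaks)}\n")
            frame.to_csv(fh, sep="\t", float_format="%.10g", index=False)
        written["trajectory"] = path
    return written
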