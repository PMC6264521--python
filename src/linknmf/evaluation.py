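"""Evaluation of link-prediction scores and the repeated-experiment harness.

AUC here is the probability that a randomly chosen probe link (held-out true
edge) scores higher than a randomly chosen nonexistent link (a pair absent
from the full network), ties counted half:

    AUC = (n' + 0.5 n'') / n

over n comparisons with n' strict wins and n'' ties. Precision@L is the
fraction of the L top-ranked candidate pairs that are probe links (L = 100
by convention). The harness repeats random edge splits over a range of
training fractions, scoring every requested method on the same splits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .attributes import ATTRIBUTE_METRICS
from .factorization import JointNMF, PlainNMF, ScoreMatrix, build_inputs
from .graph import AttributeTable, EdgeSplit, Graph, split_edges
from .similarity import STRUCTURAL_METHODS, structural_similarity

__all__ = [
    "AUCResult",
    "PrecisionResult",
    "auc",
    "precision_at_L",
    "score_method",
    "run_experiment",
    "sensitivity_sweep",
    "DEFAULT_TRAIN_FRACTIONS",
]

DEFAULT_TRAIN_FRACTIONS = (0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2)

# exhaustive comparison is used below this many probe x nonexistent pairs
_EXHAUSTIVE_LIMIT = 10**6
_DEFAULT_SAMPLES = 10**5


@dataclass(frozen=True)
class AUCResult:
    n_comparisons: int
    n_higher: int
    n_tied: int
    mode: str  # "exhaustive" | "sampled"

    @property
    def auc(self) -> float:
        return (self.n_higher + 0.5 * self.n_tied) / self.n_comparisons


@dataclass(frozen=True)
class PrecisionResult:
    L: int
    n_correct: int

    @property
    def precision(self) -> float:
        return self.n_correct / self.L


def _nonexistent_mask(full_graph: Graph) -> np.ndarray:
    """Upper-triangle mask of pairs absent from the FULL graph (U \\ E)."""
    A = full_graph.adjacency(dtype=bool)
    return np.triu(~A, k=1)


def auc(
    scores: ScoreMatrix,
    probe_edges,
    full_graph: Graph,
    n_samples: int | str = "auto",
    seed: int = 0,
) -> AUCResult:
    """AUC of probe links vs nonexistent links.

    ``n_samples`` may be "exhaustive" (enumerate all probe x nonexistent
    pairs), an integer (that many independent comparisons sampled with
    replacement), or "auto" (exhaustive while the product of set sizes is at
    most 1e6, else 1e5 samples). Nonexistent links are pairs missing from
    the full graph, so probe links are never counted as nonexistent.
    """
    probe = sorted(probe_edges)
    if not probe:
        raise ValueError("probe set is empty")
    pidx = np.array(probe)
    p = scores.values[pidx[:, 0], pidx[:, 1]]

    ne_mask = _nonexistent_mask(full_graph)
    q = scores.values[ne_mask]
    if q.size == 0:
        raise ValueError("no nonexistent pairs available")

    if n_samples == "auto":
        n_samples = (
            "exhaustive" if p.size * q.size <= _EXHAUSTIVE_LIMIT else _DEFAULT_SAMPLES
        )
    if n_samples == "exhaustive":
        qs = np.sort(q)
        lo = np.searchsorted(qs, p, side="left")
        hi = np.searchsorted(qs, p, side="right")
        n_higher = int(lo.sum())
        n_tied = int((hi - lo).sum())
        return AUCResult(
            n_comparisons=p.size * q.size,
            n_higher=n_higher,
            n_tied=n_tied,
            mode="exhaustive",
        )
    n_samples = int(n_samples)
    rng = np.random.default_rng(seed)
    ps = p[rng.integers(0, p.size, n_samples)]
    qs = q[rng.integers(0, q.size, n_samples)]
    return AUCResult(
        n_comparisons=n_samples,
        n_higher=int((ps > qs).sum()),
        n_tied=int((ps == qs).sum()),
        mode="sampled",
    )


def precision_at_L(
    scores: ScoreMatrix,
    probe_edges,
    L: int = 100,
    seed: int = 0,
) -> PrecisionResult:
    """Fraction of the top-L ranked candidate pairs that are probe links.

    Candidates are the unobserved non-self pairs of the training graph
    (``scores.candidate_mask``); ties are broken by a seeded random shuffle.
    """
    mask = np.triu(scores.candidate_mask, k=1)
    ii, jj = np.nonzero(mask)
    if ii.size < L:
        raise ValueError(f"only {ii.size} candidate pairs, need L={L}")
    vals = scores.values[ii, jj]
    rng = np.random.default_rng(seed)
    tiebreak = rng.permutation(ii.size)
    order = np.lexsort((tiebreak, -vals))[:L]
    probe = set(map(tuple, map(sorted, probe_edges)))
    n_correct = sum((int(ii[t]), int(jj[t])) in probe for t in order)
    return PrecisionResult(L=L, n_correct=n_correct)


def _parse_method(spec: str) -> tuple[str, dict]:
    """Parse a method label like "CN", "NMF", "JointNMF:A+Sim:AA", "Random"."""
    parts = spec.split(":")
    name = parts[0]
    if name in STRUCTURAL_METHODS or name in ("NMF", "Random"):
        if len(parts) != 1:
            raise ValueError(f"method {spec!r} takes no arguments")
        return name, {}
    if name == "JointNMF":
        if len(parts) < 2:
            raise ValueError(f"method {spec!r} needs a combination mode")
        mode = parts[1]
        sim_method = parts[2] if len(parts) > 2 else None
        return name, {"mode": mode, "sim_method": sim_method}
    raise ValueError(
        f"unknown method {spec!r}; valid: structural indices "
        f"{sorted(STRUCTURAL_METHODS)}, 'NMF', 'Random', or "
        "'JointNMF:<mode>[:<sim_method>]'"
    )


def score_method(
    method: str,
    split: EdgeSplit,
    attrs: AttributeTable | None = None,
    nmf_params: dict | None = None,
    attr_metric: str = "cosine",
    seed: int = 0,
) -> tuple[ScoreMatrix, dict]:
    """Score every candidate pair of a split with one method.

    Returns the score matrix and a dict of fit metadata (iterations,
    convergence) for factorization methods.
    """
    name, opts = _parse_method(method)
    train = split.train_graph
    A = train.adjacency()
    mask = (A == 0) & ~np.eye(train.n_nodes, dtype=bool)
    meta = {"iterations": 0, "converged": True, "mode": opts.get("mode", "")}
    params = dict(nmf_params or {})

    if name in STRUCTURAL_METHODS:
        sim = structural_similarity(train, name)
        return ScoreMatrix(values=sim.values, candidate_mask=mask), meta
    if name == "Random":
        rng = np.random.default_rng(seed)
        R = rng.random((train.n_nodes, train.n_nodes))
        return ScoreMatrix(values=(R + R.T) / 2, candidate_mask=mask), meta
    if name == "NMF":
        params.pop("alpha", None)
        params.pop("beta", None)
        model = PlainNMF(random_state=seed, **params)
        sm = model.fit_predict_scores(A)
    else:
        A_in, S_in = build_inputs(
            train, attrs, attr_metric=attr_metric, **opts
        )
        model = JointNMF(random_state=seed, **params)
        sm = model.fit_predict_scores(A_in, S_in)
        # candidates are always the train graph's unobserved pairs, even in
        # Sim+S mode where the factor target is not the adjacency
        sm = ScoreMatrix(values=sm.values, candidate_mask=mask)
    meta.update(iterations=model.n_iter_, converged=model.converged_)
    return sm, meta


def _derive_seed(master_seed: int, *keys: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), *map(int, keys)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_experiment(
    graph: Graph,
    attrs: AttributeTable | None,
    methods,
    train_fractions=DEFAULT_TRAIN_FRACTIONS,
    repetitions: int = 100,
    master_seed: int = 0,
    nmf_params: dict | None = None,
    attr_metric: str = "cosine",
    L: int = 100,
    auc_samples: int | str = "auto",
) -> pd.DataFrame:
    """Repeated-split evaluation of several methods on one network.

    For each (fraction, repetition) a split seed is derived deterministically
    from the master seed, and every method is scored on that same split —
    paired comparisons across methods. Returns one row per
    (method, fraction, repetition) with AUC and precision; aggregate with
    ``df.groupby(["method", "train_fraction"]).mean(numeric_only=True)``.
    """
    for m in methods:
        name, opts = _parse_method(m)
        if name == "JointNMF" and opts["mode"] in ("A+S", "Sim+S") and attrs is None:
            raise ValueError(f"method {m!r} requires an attribute table")
    rows = []
    for fi, frac in enumerate(train_fractions):
        for rep in range(repetitions):
            split_seed = _derive_seed(master_seed, fi, rep)
            split = split_edges(graph, frac, seed=split_seed)
            for m in methods:
                sm, meta = score_method(
                    m,
                    split,
                    attrs=attrs,
                    nmf_params=nmf_params,
                    attr_metric=attr_metric,
                    seed=_derive_seed(master_seed, fi, rep, 1),
                )
                a = auc(
                    sm,
                    split.probe_edges,
                    graph,
                    n_samples=auc_samples,
                    seed=_derive_seed(master_seed, fi, rep, 2),
                )
                prec = precision_at_L(
                    sm,
                    split.probe_edges,
                    L=L,
                    seed=_derive_seed(master_seed, fi, rep, 3),
                )
                rows.append(
                    {
                        "method": m,
                        "mode": meta["mode"],
                        "train_fraction": frac,
                        "repetition": rep,
                        "auc": a.auc,
                        "precision": prec.precision,
                        "iterations": meta["iterations"],
                        "converged": meta["converged"],
                    }
                )
    return pd.DataFrame(rows)


def sensitivity_sweep(
    graph: Graph,
    attrs: AttributeTable | None,
    alpha_values,
    beta_values,
    method: str = "JointNMF:A+S",
    train_fraction: float = 0.9,
    repetitions: int = 10,
    master_seed: int = 0,
    nmf_params: dict | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Mean AUC/precision over a grid of (alpha, beta) at one train fraction.

    Returns a tidy frame with one row per grid cell, suitable for pivoting
    into a heat map.
    """
    if not alpha_values or not beta_values:
        raise ValueError("alpha_values and beta_values must be non-empty")
    cells = []
    for a in alpha_values:
        for b in beta_values:
            params = dict(nmf_params or {})
            params.update(alpha=a, beta=b)
            df = run_experiment(
                graph,
                attrs,
                [method],
                train_fractions=[train_fraction],
                repetitions=repetitions,
                master_seed=master_seed,
                nmf_params=params,
                **kwargs,
            )
            cells.append(
                {
                    "alpha": a,
                    "beta": b,
                    "auc": df["auc"].mean(),
                    "precision": df["precision"].mean(),
                }
            )
    return pd.DataFrame(cells)
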