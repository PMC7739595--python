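"""Queries on fitted networks.

Conditional probability queries use likelihood weighting: ancestral
sampling with evidence nodes clamped, each sample weighted by the
conditional probability (density, for continuous evidence) of the
clamped values given its sampled parents.  Small discrete networks can
be queried exactly by joint enumeration, which serves as the oracle for
the sampler.  The module also provides Markov blankets, exhaustive
evidence-combination tables, conditional sampling of node subsets and
a conjugate Bayesian linear regression for downstream effect summaries.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from stressnet.bn.dag import Dag
from stressnet.bn.fit import DiscreteBayesNet, HybridBayesNet, CPT


class ImpossibleEvidenceError(ValueError):
    """Evidence has probability (all sample weights) zero under the network."""


@dataclass(frozen=True)
class EvidenceQuery:
    """A conditional probability query Pr(event | evidence)."""

    event: dict[str, str]
    evidence: dict[str, object] = field(default_factory=dict)
    n_samples: int = 100_000
    seed: int | None = None

    def __post_init__(self):
        if not self.event:
            raise ValueError("event must name at least one node/state")
        clash = set(self.event) & set(self.evidence)
        if clash:
            raise ValueError(f"nodes in both event and evidence: {sorted(clash)}")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass(frozen=True)
class QueryResult:
    probability: float
    std_error: float
    effective_samples: float
    n_samples: int

    def __post_init__(self):
        if not (-1e-12 <= self.probability <= 1 + 1e-12):
            raise ValueError("probability outside [0, 1]")
        if self.std_error < 0:
            raise ValueError("standard error must be >= 0")


def markov_blanket(dag: Dag, node: str) -> frozenset[str]:
    """Parents, children and co-parents of ``node`` (spouses), excluding it."""
    if node not in dag.nodes:
        raise KeyError(f"unknown node {node!r}")
    blanket = set(dag.parents(node)) | set(dag.children(node))
    for child in dag.children(node):
        blanket |= set(dag.parents(child))
    blanket.discard(node)
    return frozenset(blanket)


def _check_query(net, q: EvidenceQuery) -> None:
    known = set(net.nodes)
    for n in itertools.chain(q.event, q.evidence):
        if n not in known:
            raise KeyError(f"unknown node {n!r}")


def _state_code(net, node: str, state: str) -> int:
    states = net.states[node]
    try:
        return states.index(state)
    except ValueError:
        raise KeyError(f"unknown state {state!r} for node {node!r} (states: {states})")


def _sample_with_weights(
    net: DiscreteBayesNet | HybridBayesNet,
    evidence: dict[str, object],
    n: int,
    rng: np.random.Generator,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Ancestral sampling with clamped evidence; returns samples and log-weights."""
    hybrid = isinstance(net, HybridBayesNet)
    gaussians = net.gaussians if hybrid else {}
    samples: dict[str, np.ndarray] = {}
    logw = np.zeros(n)
    for node in net.dag.topological_order():
        if node in gaussians:
            lg = gaussians[node]
            cfg = CPT(
                parents=lg.disc_parents,
                parent_cards=lg.disc_cards,
                states=(),
                table=np.empty((0, 0)),
            ).row_index(np.vstack([samples[p] for p in lg.disc_parents]) if lg.disc_parents else np.zeros((0, n), dtype=np.int64))
            mean = lg.coef[cfg, 0].copy()
            for j, p in enumerate(lg.cont_parents):
                mean += lg.coef[cfg, 1 + j] * samples[p]
            sd = lg.sd[cfg]
            if node in evidence:
                val = float(evidence[node])  # type: ignore[arg-type]
                samples[node] = np.full(n, val)
                logw += stats.norm.logpdf(val, loc=mean, scale=sd)
            else:
                samples[node] = mean + sd * rng.standard_normal(n)
        else:
            cpt = net.cpts[node]
            if cpt.parents:
                cfg = cpt.row_index(np.vstack([samples[p] for p in cpt.parents]))
            else:
                cfg = np.zeros(n, dtype=np.int64)
            rows = cpt.table[cfg]
            if node in evidence:
                code = _state_code(net, node, str(evidence[node]))
                samples[node] = np.full(n, code, dtype=np.int64)
                p = rows[np.arange(n), code]
                with np.errstate(divide="ignore"):
                    logw += np.log(p)
            else:
                u = rng.random(n)
                samples[node] = (rows.cumsum(axis=1) < u[:, None]).sum(axis=1).astype(np.int64)
    return samples, logw


def cpquery_lw(
    net: DiscreteBayesNet | HybridBayesNet,
    q: EvidenceQuery,
) -> QueryResult:
    """Estimate Pr(event | evidence) by likelihood weighting.

    The estimate is the weighted fraction of samples satisfying the
    event; its Monte-Carlo standard error comes from the usual
    ratio-estimator linearisation.  Raises
    :class:`ImpossibleEvidenceError` when every sample weight is zero.
    """
    _check_query(net, q)
    rng = np.random.default_rng(q.seed)
    samples, logw = _sample_with_weights(net, q.evidence, q.n_samples, rng)
    finite = np.isfinite(logw)
    w = np.zeros(q.n_samples)
    if finite.any():
        shift = logw[finite].max()
        w[finite] = np.exp(logw[finite] - shift)
    wsum = w.sum()
    if wsum <= 0:
        raise ImpossibleEvidenceError("evidence has zero probability under the network")
    indicator = np.ones(q.n_samples, dtype=bool)
    for node, state in q.event.items():
        indicator &= samples[node] == _state_code(net, node, state)
    x = indicator.astype(float)
    p_hat = float((w * x).sum() / wsum)
    # Ratio-estimator variance: Var(sum w (x - p)) / (sum w)^2.
    resid = w * (x - p_hat)
    se = float(np.sqrt((resid**2).sum()) / wsum)
    ess = float(wsum**2 / (w**2).sum())
    return QueryResult(
        probability=min(max(p_hat, 0.0), 1.0),
        std_error=se,
        effective_samples=ess,
        n_samples=q.n_samples,
    )


def exact_query(net: DiscreteBayesNet, q: EvidenceQuery) -> float:
    """Pr(event | evidence) by full joint enumeration (discrete nets only)."""
    if isinstance(net, HybridBayesNet):
        raise TypeError("exact enumeration requires a fully discrete network")
    _check_query(net, q)
    nodes = list(net.dag.topological_order())
    cards = [len(net.states[n]) for n in nodes]
    total = 1
    for c in cards:
        total *= c
    if total > 10**6:
        raise ValueError(f"joint state space too large to enumerate ({total} configurations)")
    grids = np.meshgrid(*[np.arange(c) for c in cards], indexing="ij")
    assign = {n: g.ravel().astype(np.int64) for n, g in zip(nodes, grids)}
    logp = np.zeros(total)
    for node in nodes:
        cpt = net.cpts[node]
        if cpt.parents:
            cfg = cpt.row_index(np.vstack([assign[p] for p in cpt.parents]))
        else:
            cfg = np.zeros(total, dtype=np.int64)
        with np.errstate(divide="ignore"):
            logp += np.log(cpt.table[cfg, assign[node]])
    joint = np.exp(logp)
    ev_mask = np.ones(total, dtype=bool)
    for node, state in q.evidence.items():
        ev_mask &= assign[node] == _state_code(net, node, str(state))
    denom = joint[ev_mask].sum()
    if denom <= 0:
        raise ImpossibleEvidenceError("evidence has zero probability under the network")
    mask = ev_mask.copy()
    for node, state in q.event.items():
        mask &= assign[node] == _state_code(net, node, state)
    return float(joint[mask].sum() / denom)


def blanket_query_table(
    net: DiscreteBayesNet | HybridBayesNet,
    target: tuple[str, str],
    blanket_vars: tuple[str, ...] | list[str],
    *,
    continuous_levels: tuple[float, ...] = (-1.0, 0.0, 1.0),
    continuous_labels: tuple[str, ...] = ("-1 SD", "Mean", "+1 SD"),
    n_samples: int = 100_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Pr(target | every combination of blanket-variable levels).

    Discrete variables contribute their states; continuous variables
    contribute ``continuous_levels`` (on the standardised scale, so the
    defaults mean one SD below the mean change, the mean change and one
    SD above).  Rows are sorted by descending probability and carry the
    Monte-Carlo standard error.
    """
    node, state = target
    hybrid = isinstance(net, HybridBayesNet)
    level_values: list[tuple] = []
    level_labels: list[tuple] = []
    for var in blanket_vars:
        if hybrid and var in net.gaussians:
            level_values.append(tuple(continuous_levels))
            level_labels.append(tuple(continuous_labels))
        else:
            states = net.states[var]
            level_values.append(tuple(states))
            level_labels.append(tuple(states))
    records = []
    ss = np.random.SeedSequence(seed)
    combos = list(itertools.product(*level_values)) if blanket_vars else [()]
    labels = list(itertools.product(*level_labels)) if blanket_vars else [()]
    child_seeds = ss.spawn(len(combos))
    for combo, lab, child in zip(combos, labels, child_seeds):
        evidence = dict(zip(blanket_vars, combo))
        q = EvidenceQuery(
            event={node: state},
            evidence=evidence,
            n_samples=n_samples,
            seed=int(child.generate_state(1)[0]),
        )
        res = cpquery_lw(net, q)
        rec = {"probability": res.probability, "std_error": res.std_error}
        rec.update(dict(zip(blanket_vars, lab)))
        records.append(rec)
    cols = ["probability", "std_error", *blanket_vars]
    out = pd.DataFrame(records, columns=cols)
    return out.sort_values("probability", ascending=False, ignore_index=True)


def sample_net(
    net: DiscreteBayesNet | HybridBayesNet,
    n: int,
    seed: int | None = None,
) -> pd.DataFrame:
    """``n`` ancestral draws of every node, with state labels restored."""
    return sample_conditional(net, list(net.nodes), n, seed=seed)


def sample_conditional(
    net: HybridBayesNet | DiscreteBayesNet,
    nodes: tuple[str, ...] | list[str],
    n: int,
    seed: int | None = None,
) -> pd.DataFrame:
    """``n`` joint ancestral draws of ``nodes`` (via their ancestral closure)."""
    for node in nodes:
        if node not in net.nodes:
            raise KeyError(f"unknown node {node!r}")
    rng = np.random.default_rng(seed)
    samples, _ = _sample_with_weights(net, {}, n, rng)
    out = {}
    hybrid = isinstance(net, HybridBayesNet)
    for node in nodes:
        if hybrid and node in net.gaussians:
            out[node] = samples[node]
        else:
            states = np.asarray(net.states[node], dtype=object)
            out[node] = states[samples[node]]
    return pd.DataFrame(out)


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior mean, sd and central 95% credible interval per coefficient."""

    frame: pd.DataFrame  # columns: term, estimate, error, lower, upper
    draws: pd.DataFrame  # one column per term

    def coefficient(self, term: str) -> pd.Series:
        return self.frame.set_index("term").loc[term]


def bayes_linreg(
    y: np.ndarray,
    X: np.ndarray,
    prior_sd: float = 5.0,
    *,
    names: list[str] | None = None,
    n_draws: int = 4000,
    n_burn: int = 500,
    seed: int | None = None,
) -> PosteriorSummary:
    """Bayesian linear regression with independent N(0, prior_sd^2) priors.

    An intercept column is prepended to ``X``.  Sampling is a Gibbs
    scheme alternating the conjugate normal draw of the coefficients
    with an inverse-gamma draw of the noise variance (weak
    inverse-gamma(0.01, 0.01) prior).  Summaries use the central 95%
    interval over ``n_draws`` retained draws.
    """
    if prior_sd <= 0:
        raise ValueError("prior_sd must be > 0")
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 observations")
    design = np.column_stack([np.ones(n), X])
    p = design.shape[1]
    if np.linalg.matrix_rank(design) < p:
        raise ValueError("design matrix is rank deficient")
    if names is None:
        names = ["intercept"] + [f"x{j}" for j in range(1, p)]
    else:
        names = ["intercept"] + list(names)
        if len(names) != p:
            raise ValueError("names length must match number of predictors")

    rng = np.random.default_rng(seed)
    XtX = design.T @ design
    Xty = design.T @ y
    beta_ols, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta_ols
    sigma2 = float(resid @ resid) / max(n - p, 1)
    sigma2 = max(sigma2, 1e-12)
    a0 = b0 = 0.01
    prior_prec = 1.0 / prior_sd**2
    draws = np.empty((n_draws, p))
    for t in range(n_burn + n_draws):
        A = XtX / sigma2 + prior_prec * np.eye(p)
        L = np.linalg.cholesky(A)
        mean = np.linalg.solve(A, Xty / sigma2)
        z = rng.standard_normal(p)
        beta = mean + np.linalg.solve(L.T, z)
        r = y - design @ beta
        rss = float(r @ r)
        sigma2 = float(1.0 / rng.gamma(a0 + 0.5 * n, 1.0 / (b0 + 0.5 * rss)))
        sigma2 = max(sigma2, 1e-12)
        if t >= n_burn:
            draws[t - n_burn] = beta

    lower, upper = np.percentile(draws, [2.5, 97.5], axis=0)
    frame = pd.DataFrame(
        {
            "term": names,
            "estimate": draws.mean(axis=0),
            "error": draws.std(axis=0, ddof=1),
            "lower": lower,
            "upper": upper,
        }
    )
    return PosteriorSummary(frame=frame, draws=pd.DataFrame(draws, columns=names))
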