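"""Bayesian admixture clustering via Gibbs sampling, with multi-run
management: evidence-based K selection (second-difference statistic),
label-switching alignment across runs, threshold classification, and a
hierarchical second round per cluster.

Model: each allele copy has a latent cluster of origin; cluster allele
frequencies get a symmetric Dirichlet(lambda=1) prior (independent
frequencies); individual ancestry rows get a symmetric Dirichlet(alpha)
prior with a single alpha shared across clusters, updated by a
Metropolis random-walk step under a uniform prior on (0, alpha_max].
Missing allele copies contribute no likelihood term.

Defaults mirror common practice for germplasm surveys (burn-in 1e5,
1e6 sweeps, K 1-10, 10 runs); the scaled-down mode (e.g. burn-in 2,000 /
10,000 sweeps) is a first-class, documented configuration used by the
test-suite and any desk-scale analysis.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln

from .genotypes import MISSING, GenotypeError, GenotypeMatrix

DEFAULT_BURNIN = 100_000
DEFAULT_ITERS = 1_000_000
SCALED_BURNIN = 2_000
SCALED_ITERS = 10_000


@dataclass
class AdmixtureRun:
    k: int
    q: np.ndarray  # n x K posterior-mean memberships, rows sum to 1
    p: np.ndarray  # K x L x Amax posterior-mean allele frequencies
    lnl_trace: np.ndarray  # recorded post-burn-in log-likelihoods
    ln_pd: float  # evidence approximation mean(lnL) - var(lnL)/2
    seed: int
    burnin: int
    iters: int
    alpha: float = 1.0


def _copies(gm: GenotypeMatrix):
    """Flatten typed allele copies to (ind_idx, loc_idx, allele_code) plus
    per-locus allele code tables and a validity mask."""
    n, L = gm.n_accessions, gm.n_loci
    tables = []
    amax = 1
    for j, locus in enumerate(gm.locus_ids):
        alleles = gm.alleles_at(locus)
        tables.append({a: c for c, a in enumerate(alleles)})
        amax = max(amax, len(alleles) or 1)
    valid = np.zeros((L, amax), dtype=bool)
    for j, t in enumerate(tables):
        valid[j, : len(t)] = True
        if not t:
            valid[j, 0] = True  # untyped locus: dummy slot
    ind, loc, al = [], [], []
    for j in range(L):
        typed = np.nonzero(gm.a1[:, j] != MISSING)[0]
        for arr in (gm.a1, gm.a2):
            ind.append(typed)
            loc.append(np.full(len(typed), j))
            al.append(np.array([tables[j][int(v)] for v in arr[typed, j]], dtype=int))
    return (
        np.concatenate(ind),
        np.concatenate(loc),
        np.concatenate(al),
        valid,
    )


def mixture_loglik(
    q: np.ndarray,
    p: np.ndarray,
    ind_idx: np.ndarray,
    loc_idx: np.ndarray,
    al_idx: np.ndarray,
) -> float:
    """Observed-data log-likelihood sum_copies ln(sum_k q_ik p_kla).

    Invariant under any simultaneous permutation of the cluster labels of
    q and p."""
    w = (q[ind_idx, :] * p[:, loc_idx, al_idx].T).sum(axis=1)
    return float(np.log(np.maximum(w, 1e-300)).sum())


def run_admixture(
    gm: GenotypeMatrix,
    k: int,
    burnin: int = DEFAULT_BURNIN,
    iters: int = DEFAULT_ITERS,
    seed: int | None = None,
    thin: int = 10,
    lam: float = 1.0,
    alpha0: float = 1.0,
    update_alpha: bool = True,
    alpha_sd: float = 0.025,
    alpha_max: float = 10.0,
) -> AdmixtureRun:
    """One MCMC run at a fixed cluster count *k*.

    Q and P are posterior means over post-burn-in samples recorded every
    *thin* sweeps; ln_pd is the evidence approximation
    mean(lnL) - var(lnL)/2 over the recorded trace.  *seed* is mandatory.
    """
    if k < 1:
        raise GenotypeError(f"cluster count must be >= 1, got {k}")
    if seed is None:
        raise GenotypeError("seed is mandatory")
    if iters < thin:
        raise GenotypeError(
            f"iters={iters} leaves no recorded samples (thin={thin})"
        )
    rng = np.random.default_rng(seed)
    n, L = gm.n_accessions, gm.n_loci
    ind_idx, loc_idx, al_idx, valid = _copies(gm)
    amax = valid.shape[1]
    m = len(ind_idx)

    q = rng.dirichlet(np.ones(k), size=n)
    g = rng.gamma(lam, size=(k, L, amax)) * valid[None, :, :]
    p = g / np.maximum(g.sum(axis=2, keepdims=True), 1e-300)
    alpha = alpha0

    q_sum = np.zeros_like(q)
    p_sum = np.zeros_like(p)
    lnl_trace: list[float] = []
    n_rec = 0

    for t in range(burnin + iters):
        # latent cluster of origin per allele copy
        w = q[ind_idx, :] * p[:, loc_idx, al_idx].T  # (m, k)
        cs = np.cumsum(w, axis=1)
        u = rng.random(m) * cs[:, -1]
        z = (cs < u[:, None]).sum(axis=1)
        np.clip(z, 0, k - 1, out=z)
        # cluster allele frequencies
        cnt = np.zeros((k, L, amax))
        np.add.at(cnt, (z, loc_idx, al_idx), 1.0)
        g = rng.gamma(lam + cnt) * valid[None, :, :]
        p = g / np.maximum(g.sum(axis=2, keepdims=True), 1e-300)
        np.maximum(p, 1e-12, out=p)
        p *= valid[None, :, :]
        p /= np.maximum(p.sum(axis=2, keepdims=True), 1e-300)
        # individual memberships
        qc = np.zeros((n, k))
        np.add.at(qc, (ind_idx, z), 1.0)
        g = rng.gamma(alpha + qc)
        g = np.maximum(g, 1e-300)
        q = g / g.sum(axis=1, keepdims=True)
        np.maximum(q, 1e-12, out=q)
        q /= q.sum(axis=1, keepdims=True)
        # shared concentration parameter
        if update_alpha and k > 1:
            prop = alpha + rng.normal(0.0, alpha_sd)
            if 0.0 < prop <= alpha_max:
                slq = float(np.log(q).sum())
                lr = n * (
                    gammaln(k * prop)
                    - k * gammaln(prop)
                    - gammaln(k * alpha)
                    + k * gammaln(alpha)
                ) + (prop - alpha) * slq
                if math.log(rng.random()) < lr:
                    alpha = prop
        if t >= burnin and (t - burnin) % thin == 0:
            q_sum += q
            p_sum += p
            lnl_trace.append(mixture_loglik(q, p, ind_idx, loc_idx, al_idx))
            n_rec += 1

    q_mean = q_sum / n_rec
    q_mean /= q_mean.sum(axis=1, keepdims=True)
    p_mean = p_sum / n_rec
    trace = np.array(lnl_trace)
    var = float(trace.var(ddof=1)) if len(trace) > 1 else 0.0
    ln_pd = float(trace.mean()) - var / 2.0
    if k == 1:
        q_mean = np.ones((n, 1))
    return AdmixtureRun(
        k=k,
        q=q_mean,
        p=p_mean,
        lnl_trace=trace,
        ln_pd=ln_pd,
        seed=int(seed),
        burnin=burnin,
        iters=iters,
        alpha=float(alpha),
    )


def run_k_scan(
    gm: GenotypeMatrix,
    k_min: int = 1,
    k_max: int = 10,
    runs_per_k: int = 10,
    burnin: int = DEFAULT_BURNIN,
    iters: int = DEFAULT_ITERS,
    seed: int | None = None,
    **kwargs,
) -> dict[int, list[AdmixtureRun]]:
    """Independent runs for each K in [k_min, k_max], with per-run seeds
    derived deterministically from *seed*."""
    if seed is None:
        raise GenotypeError("seed is mandatory")
    ss = np.random.SeedSequence(seed)
    out: dict[int, list[AdmixtureRun]] = {}
    for k in range(k_min, k_max + 1):
        out[k] = [
            run_admixture(
                gm, k, burnin=burnin, iters=iters,
                seed=int(child.generate_state(1)[0] % (2**31)), **kwargs,
            )
            for child in ss.spawn(runs_per_k)
        ]
    return out


# -- K selection -----------------------------------------------------------


@dataclass
class EvannoTable:
    ks: list[int]
    mean_lnpd: dict[int, float]
    sd_lnpd: dict[int, float]
    l_prime: dict[int, float]  # defined for K > Kmin
    l_second: dict[int, float]  # |L''|, defined for Kmin < K < Kmax
    delta_k: dict[int, float]
    best_k: int

    def to_rows(self) -> list[dict]:
        rows = []
        for k in self.ks:
            rows.append(
                {
                    "K": k,
                    "mean_lnPD": self.mean_lnpd[k],
                    "sd_lnPD": self.sd_lnpd[k],
                    "L_prime": self.l_prime.get(k),
                    "abs_L_second": self.l_second.get(k),
                    "delta_K": self.delta_k.get(k),
                }
            )
        return rows


def evanno(runs_by_k: Mapping[int, Sequence]) -> EvannoTable:
    """Second-difference K-selection statistic.

    L'(K) = mean lnPD(K) - mean lnPD(K-1); |L''(K)| = |L'(K+1) - L'(K)|;
    DeltaK = |L''(K)| / sd(lnPD at K), defined for interior K only.
    Accepts AdmixtureRun sequences or plain lnPD numbers per K.  A zero sd
    yields +inf with a warning (flagged, never dropped); best_k is the
    argmax of DeltaK (ties -> smaller K).
    """
    ks = sorted(runs_by_k)
    if len(ks) < 3:
        raise GenotypeError("need >= 3 consecutive K values")
    if any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise GenotypeError("K values must be consecutive")
    mean_lnpd: dict[int, float] = {}
    sd_lnpd: dict[int, float] = {}
    for k in ks:
        vals = [
            r.ln_pd if isinstance(r, AdmixtureRun) else float(r)
            for r in runs_by_k[k]
        ]
        if len(vals) < 2:
            raise GenotypeError(f"K={k}: need >= 2 runs for a standard deviation")
        arr = np.array(vals)
        mean_lnpd[k] = float(arr.mean())
        sd_lnpd[k] = float(arr.std(ddof=1))
    l_prime = {k: mean_lnpd[k] - mean_lnpd[k - 1] for k in ks[1:]}
    l_second = {k: abs(l_prime[k + 1] - l_prime[k]) for k in ks[1:-1]}
    delta_k: dict[int, float] = {}
    for k in ks[1:-1]:
        if sd_lnpd[k] == 0.0:
            warnings.warn(
                f"K={k}: zero sd of lnPD across runs; DeltaK reported as +inf",
                stacklevel=2,
            )
            delta_k[k] = float("inf")
        else:
            delta_k[k] = l_second[k] / sd_lnpd[k]
    best_k = min(
        (k for k in delta_k),
        key=lambda k: (-delta_k[k], k),
    )
    return EvannoTable(ks, mean_lnpd, sd_lnpd, l_prime, l_second, delta_k, best_k)


# -- run alignment ---------------------------------------------------------


@dataclass
class AlignmentResult:
    aligned_q: list[np.ndarray]
    permutations: list[tuple[int, ...]]
    mean_similarity: float  # mean pairwise G over aligned runs

    @property
    def mean_q(self) -> np.ndarray:
        q = np.mean(self.aligned_q, axis=0)
        return q / q.sum(axis=1, keepdims=True)


def _similarity(q1: np.ndarray, q2: np.ndarray) -> float:
    n = q1.shape[0]
    return 1.0 - float(np.linalg.norm(q1 - q2)) / math.sqrt(2.0 * n)


def _best_permutation(q_ref: np.ndarray, q: np.ndarray) -> tuple[int, ...]:
    k = q.shape[1]
    if k <= 8:
        best, best_cost = None, np.inf
        for perm in itertools.permutations(range(k)):
            cost = float(((q_ref - q[:, perm]) ** 2).sum())
            if cost < best_cost - 1e-15:
                best, best_cost = perm, cost
        return best
    # Frobenius cost decomposes over column pairs, so the assignment
    # problem is solved exactly above K=8 as well
    cost = ((q_ref[:, :, None] - q[:, None, :]) ** 2).sum(axis=0)
    _, cols = linear_sum_assignment(cost)
    return tuple(int(c) for c in cols)


def align_runs_greedy(
    runs: Sequence[AdmixtureRun] | Sequence[np.ndarray],
) -> AlignmentResult:
    """Align cluster labels across runs at one K against the first run.

    For each run the column permutation maximizing the similarity
    G = 1 - ||Q_ref - Q_perm||_F / sqrt(2n) is chosen (exhaustive over K!
    permutations for K <= 8, exact assignment above).  Returns the permuted
    Q matrices and the achieved mean pairwise G.
    """
    qs = [r.q if isinstance(r, AdmixtureRun) else np.asarray(r) for r in runs]
    if not qs:
        raise GenotypeError("no runs to align")
    shape = qs[0].shape
    if any(q.shape != shape for q in qs):
        raise GenotypeError("runs have mismatched Q shapes")
    ref = qs[0]
    aligned = [ref]
    perms: list[tuple[int, ...]] = [tuple(range(shape[1]))]
    for q in qs[1:]:
        perm = _best_permutation(ref, q)
        perms.append(perm)
        aligned.append(q[:, perm])
    sims = [
        _similarity(aligned[a], aligned[b])
        for a in range(len(aligned))
        for b in range(a + 1, len(aligned))
    ]
    mean_sim = float(np.mean(sims)) if sims else 1.0
    return AlignmentResult(aligned, perms, mean_sim)


def assign_memberships(
    q: np.ndarray, threshold: float = 0.70
) -> list[object]:
    """Classify rows of an (averaged, aligned) Q matrix.

    Label = argmax cluster index when max q >= threshold (inclusive), else
    the string ``"admixed"``.  *threshold* must lie in (1/K, 1]."""
    q = np.asarray(q, dtype=float)
    k = q.shape[1]
    if not (1.0 / k < threshold <= 1.0):
        raise GenotypeError(
            f"threshold {threshold} outside (1/{k}, 1]"
        )
    if not np.allclose(q.sum(axis=1), 1.0, atol=1e-6):
        raise GenotypeError("Q rows must sum to 1")
    labels: list[object] = []
    for row in q:
        top = int(np.argmax(row))
        labels.append(top if row[top] >= threshold else "admixed")
    return labels


# -- hierarchical second round ---------------------------------------------


@dataclass
class SecondRound:
    group: object
    accessions: list[str]
    evanno: EvannoTable | None
    labels: dict[str, object]  # accession -> nested label
    low_confidence: bool = False


def hierarchical_rounds(
    gm: GenotypeMatrix,
    first_labels: Mapping[str, object],
    k_min: int = 1,
    k_max: int = 5,
    runs_per_k: int = 3,
    burnin: int = SCALED_BURNIN,
    iters: int = SCALED_ITERS,
    seed: int | None = None,
    threshold: float = 0.70,
    min_delta_k: float = 5.0,
    **kwargs,
) -> dict[object, SecondRound]:
    """Re-run the full scan/evanno/align/assign stack independently on each
    first-round cluster (including the admixed group).

    Subsets smaller than 2 * k_max accessions are skipped with a warning.
    A best K whose DeltaK peak is below *min_delta_k* is flagged
    low-confidence.  The union of second-round subsets reproduces each
    first-round cluster.
    """
    if seed is None:
        raise GenotypeError("seed is mandatory")
    ss = np.random.SeedSequence(seed)
    groups = sorted({str(v) for v in first_labels.values()})
    out: dict[object, SecondRound] = {}
    for gi, group in enumerate(groups):
        accs = [a for a in gm.accession_ids if str(first_labels.get(a)) == group]
        if len(accs) < 2 * k_max:
            warnings.warn(
                f"group {group!r}: only {len(accs)} accessions "
                f"(< {2 * k_max}); skipped",
                stacklevel=2,
            )
            out[group] = SecondRound(group, accs, None, {a: group for a in accs})
            continue
        sub = gm.subset(accessions=accs)
        sub_seed = int(
            np.random.SeedSequence([seed, gi]).generate_state(1)[0] % (2**31)
        )
        runs = run_k_scan(
            sub, k_min=k_min, k_max=k_max, runs_per_k=runs_per_k,
            burnin=burnin, iters=iters, seed=sub_seed, **kwargs,
        )
        ev = evanno(runs)
        best = ev.best_k
        aligned = align_runs_greedy(runs[best])
        labels = assign_memberships(aligned.mean_q, threshold=threshold)
        low_conf = (
            math.isfinite(ev.delta_k.get(best, float("nan")))
            and ev.delta_k[best] < min_delta_k
        )
        out[group] = SecondRound(
            group,
            accs,
            ev,
            {a: f"{group}.{l}" for a, l in zip(accs, labels)},
            low_confidence=low_conf,
        )
    return out


def membership_barplot(q: np.ndarray, path, labels: Sequence[str] | None = None):
    """Stacked-bar export of a membership matrix (simple plot, optional)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    q = np.asarray(q)
    n, k = q.shape
    fig, ax = plt.subplots(figsize=(max(6, n * 0.05), 2.5))
    bottom = np.zeros(n)
    x = np.arange(n)
    for c in range(k):
        ax.bar(x, q[:, c], bottom=bottom, width=1.0)
        bottom += q[:, c]
    ax.set_xlim(-0.5, n - 0.5)
    ax.set_ylim(0, 1)
    ax.set_ylabel("q")
    ax.set_xticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
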