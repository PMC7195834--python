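"""HKY substitution model and Felsenstein pruning likelihood.

The HKY rate matrix is scaled so branch lengths are expected substitutions
per site.  Among-site rate variation uses the usual discrete-gamma
approximation (category rates at quantile midpoints, mean normalised to 1).
A brute-force likelihood that sums over all ancestral state combinations is
provided as an independent reference for small trees.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy.stats import gamma as gamma_dist

from .trees import IndexedTree

__all__ = [
    "HKYModel",
    "discrete_gamma_rates",
    "PruningLikelihood",
    "loglik_bruteforce",
    "encode_alignment",
    "VERTEBRATE_MITO_STOPS",
    "hky_distance_expectation",
]

# TAA/TAG are canonical stops; AGA/AGG are stops in the vertebrate
# mitochondrial code.
VERTEBRATE_MITO_STOPS = frozenset({"TAA", "TAG", "AGA", "AGG"})

_BASES = "ACGT"
_TRANSITION = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T


class HKYModel:
    """HKY85 with transition/transversion ratio kappa and base frequencies."""

    def __init__(self, kappa: float, freqs):
        freqs = np.asarray(freqs, dtype=float)
        if kappa <= 0:
            raise ValueError("kappa must be positive")
        if freqs.shape != (4,) or abs(freqs.sum() - 1) > 1e-9 or (freqs <= 0).any():
            raise ValueError("freqs must be 4 positive values summing to 1")
        self.kappa = float(kappa)
        self.freqs = freqs
        Q = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                Q[i, j] = freqs[j] * (kappa if (i, j) in _TRANSITION else 1.0)
        Q[np.diag_indices(4)] = -Q.sum(axis=1)
        mu = -(freqs * np.diag(Q)).sum()  # mean rate at stationarity
        self.Q = Q / mu
        # HKY is reversible: symmetrise to get a stable eigendecomposition
        d = np.sqrt(freqs)
        S = (self.Q * d[:, None]) / d[None, :]
        w, V = np.linalg.eigh((S + S.T) / 2.0)
        self._w = w
        self._U = V / d[:, None]  # D^{-1/2} V
        self._Uinv = V.T * d[None, :]  # V^T D^{1/2}

    def transition_matrix(self, dist: float) -> np.ndarray:
        """P(dist) for a branch of `dist` expected substitutions/site."""
        return self.transition_matrices(np.array([dist]))[0]

    def transition_matrices(self, dists: np.ndarray) -> np.ndarray:
        dists = np.asarray(dists, dtype=float)
        if (dists < 0).any():
            raise ValueError("negative branch length")
        E = np.exp(np.multiply.outer(dists, self._w))  # (k, 4)
        P = np.einsum("ij,kj,jl->kil", self._U, E, self._Uinv)
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=2, keepdims=True)
        return P


def hky_distance_expectation(dist: float, kappa: float, freqs) -> float:
    """Expected proportion of differing sites between two sequences whose
    paths sum to `dist` substitutions/site (used as a closed-form check)."""
    model = HKYModel(kappa, freqs)
    P = model.transition_matrix(dist)
    pi = model.freqs
    return float(1.0 - (pi * np.diag(P)).sum())


def discrete_gamma_rates(alpha: float, ncat: int) -> np.ndarray:
    """Mean-one discrete gamma category rates (quantile midpoints)."""
    if ncat == 1:
        return np.ones(1)
    q = (np.arange(ncat) + 0.5) / ncat
    rates = gamma_dist.ppf(q, alpha, scale=1.0 / alpha)
    return rates / rates.mean()


def encode_alignment(records: list[tuple[str, str]]) -> dict[str, np.ndarray]:
    """Map label -> int-coded sequence; ambiguity and gaps become -1."""
    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(_BASES):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    out = {}
    for label, seq in records:
        arr = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
        out[label] = arr.astype(np.int8)
    return out


class PruningLikelihood:
    """Felsenstein pruning on a fixed topology with compressed site patterns.

    Parameters
    ----------
    itree : IndexedTree
    records : list of (label, sequence); labels must match the tree's tips.
    """

    def __init__(self, itree: IndexedTree, records: list[tuple[str, str]]):
        coded = encode_alignment(records)
        missing = set(itree.tip_labels) - set(coded)
        if missing:
            raise ValueError(f"alignment is missing tips: {sorted(missing)}")
        mat = np.stack([coded[lbl] for lbl in itree.tip_labels])
        if mat.ndim != 2:
            raise ValueError("sequences must share one length")
        patterns, self.weights = np.unique(mat, axis=1, return_counts=True)
        self.n_sites = mat.shape[1]
        self.itree = itree
        n_pat = patterns.shape[1]
        # tip partial likelihoods: indicator, or all-ones for missing data
        self.tip_partials = np.ones((itree.n_tips, n_pat, 4))
        for t in range(itree.n_tips):
            known = patterns[t] >= 0
            self.tip_partials[t, known, :] = 0.0
            self.tip_partials[t, known, patterns[t, known]] = 1.0

    def loglik(
        self,
        branch_lengths: np.ndarray,
        model: HKYModel,
        gamma_alpha: float | None = None,
        ncat: int = 1,
    ) -> float:
        """Log-likelihood; `branch_lengths[i]` is the edge above node i
        (expected substitutions/site; the root entry is ignored)."""
        it = self.itree
        rates = (
            discrete_gamma_rates(gamma_alpha, ncat)
            if gamma_alpha is not None
            else np.ones(ncat)
        )
        n_pat = self.tip_partials.shape[1]
        site_logl = np.full((len(rates), n_pat), -np.inf)
        for ci, r in enumerate(rates):
            P = model.transition_matrices(
                np.where(np.isnan(branch_lengths), 0.0, branch_lengths) * r
            )
            partials = np.empty((it.n_nodes, n_pat, 4))
            partials[: it.n_tips] = self.tip_partials
            scale = np.zeros(n_pat)
            for i in it.postorder_internal:
                l, rch = it.children[i - it.n_tips]
                prod = (partials[l] @ P[l].T) * (partials[rch] @ P[rch].T)
                m = prod.max(axis=1)
                m[m == 0] = 1.0
                partials[i] = prod / m[:, None]
                scale += np.log(m)
            root_lik = (partials[it.root] * model.freqs).sum(axis=1)
            with np.errstate(divide="ignore"):
                site_logl[ci] = np.log(root_lik) + scale
        from scipy.special import logsumexp

        site_log = logsumexp(site_logl, axis=0) - np.log(len(rates))
        if not np.isfinite(site_log).all():
            return -np.inf
        return float((site_log * self.weights).sum())


class IncrementalPruning:
    """Pruning likelihood with partial updates for single-edge-group moves.

    Caches per-node transition matrices, scaled partials and log scaling
    factors so that a node-age proposal (which changes three edges) only
    recomputes the path from that node to the root.  One snapshot level is
    kept for reject/restore.
    """

    def __init__(self, itree: IndexedTree, records, ncat: int = 1):
        base = PruningLikelihood(itree, records)
        self.itree = itree
        self.weights = base.weights
        self.ncat = ncat
        n_pat = base.tip_partials.shape[1]
        self.n_pat = n_pat
        self.tip_partials = base.tip_partials
        n = itree.n_nodes
        self.P = np.zeros((n, ncat, 4, 4))
        self.partials = np.zeros((n, ncat, n_pat, 4))
        self.partials[: itree.n_tips] = base.tip_partials[:, None, :, :]
        self.lognorm = np.zeros((n, ncat, n_pat))
        self._snap = None
        self.model: HKYModel | None = None
        self.rates = np.ones(ncat)
        # ancestors (self included) of every node, tipward-to-rootward
        self._anc = []
        for v in range(n):
            chain = []
            u = v
            while u >= 0:
                if u >= itree.n_tips:
                    chain.append(u)
                u = itree.parent[u]
            self._anc.append(chain)
        self._post_rank = {int(v): i for i, v in enumerate(itree.postorder_internal)}

    # -- full state ---------------------------------------------------------

    def set_state(self, bl: np.ndarray, model: HKYModel,
                  gamma_alpha: float | None = None) -> float:
        self.model = model
        self.rates = (
            discrete_gamma_rates(gamma_alpha, self.ncat)
            if gamma_alpha is not None and self.ncat > 1
            else np.ones(self.ncat)
        )
        edges = [v for v in range(self.itree.n_nodes) if self.itree.parent[v] >= 0]
        self._set_P(edges, bl)
        for i in self.itree.postorder_internal:
            self._recompute_node(i)
        self._snap = None
        return self._root_loglik()

    def _set_P(self, edges, bl):
        lens = np.multiply.outer(
            np.where(np.isnan(bl[edges]), 0.0, bl[edges]), self.rates
        ).ravel()
        mats = self.model.transition_matrices(lens).reshape(
            len(edges), self.ncat, 4, 4
        )
        self.P[edges] = mats

    def _recompute_node(self, i: int):
        l, r = self.itree.children[i - self.itree.n_tips]
        pl = np.einsum("cpj,cij->cpi", self.partials[l], self.P[l])
        pr = np.einsum("cpj,cij->cpi", self.partials[r], self.P[r])
        prod = pl * pr
        m = prod.max(axis=2)
        safe = np.where(m == 0.0, 1.0, m)
        self.partials[i] = prod / safe[:, :, None]
        with np.errstate(divide="ignore"):
            self.lognorm[i] = np.log(m) + self.lognorm[l] + self.lognorm[r]

    def _root_loglik(self) -> float:
        root = self.itree.root
        lik = (self.partials[root] * self.model.freqs).sum(axis=2)  # (ncat, pat)
        with np.errstate(divide="ignore"):
            logl = np.log(lik) + self.lognorm[root]
        if self.ncat == 1:
            site = logl[0]
        else:
            from scipy.special import logsumexp as _lse

            site = _lse(logl, axis=0) - np.log(self.ncat)
        if not np.isfinite(site).all():
            return -np.inf
        return float((site * self.weights).sum())

    # -- partial proposals --------------------------------------------------

    def propose_edges(self, edges: list[int], bl: np.ndarray) -> float:
        """Update the given edges to the lengths in `bl`; snapshot for reject."""
        dirty: list[int] = []
        seen = set()
        for e in edges:
            start = self.itree.parent[e]
            # partial at parent(e) changes; walk its ancestor chain
            if start >= 0:
                for u in self._anc[start]:
                    if u not in seen:
                        seen.add(u)
                        dirty.append(u)
        dirty.sort(key=self._post_rank.__getitem__)
        self._snap = (
            list(edges),
            self.P[edges].copy(),
            dirty,
            self.partials[dirty].copy(),
            self.lognorm[dirty].copy(),
        )
        self._set_P(edges, bl)
        for u in dirty:
            self._recompute_node(u)
        return self._root_loglik()

    def propose_global(self, bl: np.ndarray, model: HKYModel,
                       gamma_alpha: float | None = None) -> float:
        """Full recompute with a whole-state snapshot (rate/kappa moves)."""
        self._snap = (
            "global",
            self.P.copy(),
            self.partials.copy(),
            self.lognorm.copy(),
            self.model,
            self.rates.copy(),
        )
        self.model = model
        self.rates = (
            discrete_gamma_rates(gamma_alpha, self.ncat)
            if gamma_alpha is not None and self.ncat > 1
            else np.ones(self.ncat)
        )
        edges = [v for v in range(self.itree.n_nodes) if self.itree.parent[v] >= 0]
        self._set_P(edges, bl)
        for i in self.itree.postorder_internal:
            self._recompute_node(i)
        return self._root_loglik()

    def reject(self):
        if self._snap is None:
            return
        if self._snap[0] == "global":
            _, P, partials, lognorm, model, rates = self._snap
            self.P = P
            self.partials = partials
            self.lognorm = lognorm
            self.model = model
            self.rates = rates
        else:
            edges, P, dirty, partials, lognorm = self._snap
            self.P[edges] = P
            self.partials[dirty] = partials
            self.lognorm[dirty] = lognorm
        self._snap = None

    def accept(self):
        self._snap = None


def loglik_bruteforce(
    itree: IndexedTree,
    records: list[tuple[str, str]],
    branch_lengths: np.ndarray,
    model: HKYModel,
    gamma_alpha: float | None = None,
    ncat: int = 1,
) -> float:
    """Reference likelihood summing over every ancestral state combination.

    Exponential in the number of internal nodes; intended for <= 4 tips.
    """
    coded = encode_alignment(records)
    mat = np.stack([coded[lbl] for lbl in itree.tip_labels])
    n_sites = mat.shape[1]
    rates = (
        discrete_gamma_rates(gamma_alpha, ncat)
        if gamma_alpha is not None
        else np.ones(ncat)
    )
    internals = list(itree.postorder_internal)
    total = 0.0
    for site in range(n_sites):
        site_lik = 0.0
        for r in rates:
            P = {
                i: model.transition_matrix(float(branch_lengths[i]) * r)
                for i in range(itree.n_nodes)
                if i != itree.root
            }
            acc = 0.0
            for combo in product(range(4), repeat=len(internals)):
                states = {n: s for n, s in zip(internals, combo)}
                p = model.freqs[states[itree.root]]
                for i in internals:
                    for c in itree.children[i - itree.n_tips]:
                        if c < itree.n_tips:
                            obs = mat[c, site]
                            if obs < 0:
                                p *= 1.0  # missing data: sum over states = 1
                            else:
                                p *= P[c][states[i], obs]
                        else:
                            p *= P[c][states[i], states[c]]
                acc += p
            site_lik += acc / len(rates)
        total += np.log(site_lik)
    return float(total)
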