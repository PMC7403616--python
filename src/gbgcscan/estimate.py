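"""Per-branch, per-category substitution-rate estimation on a fixed tree.

For each codon alignment the species tree is pruned to the species
present, branch lengths (plus kappa and omega) are fitted by maximum
likelihood under the YN98(F3X4) model with empirical positional
frequencies, and posterior expected substitution counts are decomposed
into the eight mutational categories (WS/SW/WW/SS x syn/nonsyn) by
analytic integration along each branch.  Per-category rates divide the
expected counts by the category-specific mutational opportunity
(Nei-Gojobori-style site counting weighted by the posterior ancestral
codon distribution at the branch's parent).  Focal-species rates sum the
branch rates along the path from the murine-gerbil divergence (Muridae
node) to each tip.

The likelihood machinery uses the reversibility of the model: the rate
matrix is symmetrized with the stationary frequencies and decomposed
once per (kappa, omega); per-branch transition matrices and expected-
count integrals then follow from the eigensystem in closed form, which
keeps both the optimizer and the mapping deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize

from . import codons as cd
from . import phylo

__all__ = [
    "GeneFit",
    "FitError",
    "fit_branch_lengths",
    "map_substitutions",
    "focal_rates",
    "estimate_rates",
]

_N = len(cd.SENSE_CODONS)
_OPP = cd.opportunity_matrix()


class FitError(RuntimeError):
    """Raised when an alignment cannot be fitted (too few sequences,
    non-finite likelihood, optimizer failure)."""


def _encode_alignment(alignment: dict[str, str]) -> dict[str, np.ndarray]:
    """Map each sequence to codon-state indices; codons containing
    ambiguity characters, gaps, or stops become -1 (treated as missing
    data in the likelihood)."""
    coded = {}
    for sp, seq in alignment.items():
        seq = seq.upper()
        if len(seq) % 3 != 0:
            raise cd.CodingLengthError(
                f"{sp}: length {len(seq)} not a multiple of three"
            )
        codes = np.array(
            [
                cd.CODON_INDEX.get(seq[i : i + 3], -1)
                for i in range(0, len(seq), 3)
            ],
            dtype=np.int16,
        )
        coded[sp] = codes
    lengths = {len(v) for v in coded.values()}
    if len(lengths) != 1:
        raise ValueError("sequences have unequal codon lengths")
    return coded


def _empirical_f3x4(alignment: dict[str, str]) -> np.ndarray:
    """Positional nucleotide frequencies pooled over all sequences, with a
    pseudocount of 0.5 per base so no sense codon has zero stationary
    frequency (required for the symmetrized decomposition)."""
    counts = np.full((3, 4), 0.5)
    col = {"A": 0, "C": 1, "G": 2, "T": 3}
    for seq in alignment.values():
        s = seq.upper()
        for i, b in enumerate(s):
            j = col.get(b)
            if j is not None:
                counts[i % 3, j] += 1
    return counts / counts.sum(axis=1, keepdims=True)


class _Engine:
    """Likelihood, gradient, and expected-count machinery for one gene."""

    def __init__(self, tree: phylo.TreeIndex, alignment: dict[str, str]):
        self.tree = tree
        coded = _encode_alignment(alignment)
        mat = np.stack([coded[name] for name in tree.tip_index], axis=1)
        patterns, counts = np.unique(mat, axis=0, return_counts=True)
        self.patterns = patterns          # (npat, ntips)
        self.counts = counts.astype(float)
        self.n_sites = mat.shape[0]
        self.tip_col = {node: k for k, node in enumerate(tree.tip_index.values())}
        self.pi3x4 = _empirical_f3x4(alignment)
        self.freqs = cd.codon_frequencies(self.pi3x4)
        # tip codon codes per pattern; missing codons (-1) act as all-ones
        # partials.  Dense one-hot partials are avoided: tip messages and
        # tip-side inner products use column indexing into the transition
        # matrices instead.
        npat = patterns.shape[0]
        self.tip_codes = {}
        self._tips_with_missing = set()
        for node, k in self.tip_col.items():
            self.tip_codes[node] = patterns[:, k]
            if (patterns[:, k] < 0).any():
                self._tips_with_missing.add(node)
        self.has_variation = any(
            len({c for c in row if c >= 0}) > 1 for row in patterns
        )
        self._kappa = None
        self._omega = None

    # -- model ------------------------------------------------------------
    def set_model(self, kappa: float, omega: float) -> None:
        if (kappa, omega) == (self._kappa, self._omega):
            return
        params = cd.YN98Params(kappa=kappa, omega=omega, pi=self.pi3x4)
        q = cd.build_rate_matrix(params)
        sq = np.sqrt(self.freqs)
        b = q * (sq[:, None] / sq[None, :])
        b = 0.5 * (b + b.T)               # symmetric up to round-off
        w, v = np.linalg.eigh(b)
        self.q = q
        self.eigval = w
        self.vl = v / sq[:, None]         # D^-1 V
        self.vr = (v * sq[:, None]).T     # V^T D
        self._kappa, self._omega = kappa, omega

    def transition_matrix(self, t: float) -> np.ndarray:
        p = (self.vl * np.exp(self.eigval * t)) @ self.vr
        return np.maximum(p, 0.0)

    def _integral_weights(self, t: float) -> np.ndarray:
        """J_ab = int_0^t exp(w_a s) exp(w_b (t-s)) ds, closed form."""
        w = self.eigval
        ewt = np.exp(w * t)
        den = w[:, None] - w[None, :]
        num = ewt[:, None] - ewt[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            j = num / den
        near = np.abs(den) < 1e-10
        mean_w = 0.5 * (w[:, None] + w[None, :])
        j[near] = (t * np.exp(mean_w * t))[near]
        return j

    # -- passes -----------------------------------------------------------
    def _tip_message(self, v, p):
        """Message a tip sends to its parent: P[:, code] per pattern,
        all-ones for missing codons."""
        codes = self.tip_codes[v]
        if v not in self._tips_with_missing:
            return p.T[codes]
        out = np.ones((codes.shape[0], _N))
        obs = codes >= 0
        out[obs] = p.T[codes[obs]]
        return out

    def _tip_inner(self, v, g, m):
        """sum_ij G[p,i] M[i,j] Dtip[p,j] for a tip's one-hot/ones
        partials, without materializing them."""
        codes = self.tip_codes[v]
        obs = codes >= 0
        inner = np.empty(codes.shape[0])
        if obs.any():
            inner[obs] = (g[obs] * m[:, codes[obs]].T).sum(axis=1)
        if (~obs).any():
            inner[~obs] = g[~obs] @ m.sum(axis=1)
        return inner

    def _forward(self, blens, pmats):
        tree = self.tree
        npat = self.patterns.shape[0]
        D = [None] * tree.n_nodes
        logS = [None] * tree.n_nodes
        msg = [None] * tree.n_nodes
        zero = np.zeros(npat)
        for v in tree.postorder:
            if not tree.children[v]:
                logS[v] = zero
                if v != tree.root:
                    msg[v] = self._tip_message(v, pmats[v])
                continue
            kids = tree.children[v]
            if len(kids) == 1:
                prod = msg[kids[0]].copy()
                ls = logS[kids[0]]
            else:
                prod = np.multiply(msg[kids[0]], msg[kids[1]])
                ls = logS[kids[0]] + logS[kids[1]]
                for c in kids[2:]:
                    prod *= msg[c]
                    ls = ls + logS[c]
            m = prod.max(axis=1)
            m = np.where(m > 0, m, 1.0)
            prod /= m[:, None]
            D[v] = prod
            logS[v] = ls + np.log(m)
            if v != tree.root:
                msg[v] = prod @ pmats[v].T
        f_raw = D[tree.root] @ self.freqs
        return D, logS, msg, f_raw

    def _backward(self, D, logS, msg, pmats):
        tree = self.tree
        npat = self.patterns.shape[0]
        G = [None] * tree.n_nodes
        logG = [None] * tree.n_nodes
        U = [None] * tree.n_nodes
        logU = [None] * tree.n_nodes
        U[tree.root] = np.broadcast_to(self.freqs, (npat, _N))
        logU[tree.root] = np.zeros(npat)
        for v in reversed(tree.postorder):
            if v == tree.root:
                continue
            p = tree.parent[v]
            g = U[p].copy()
            lg = logU[p].copy()
            for s in tree.children[p]:
                if s != v:
                    g *= msg[s]
                    lg += logS[s]
            m = g.max(axis=1)
            m = np.where(m > 0, m, 1.0)
            g /= m[:, None]
            lg += np.log(m)
            G[v], logG[v] = g, lg
            U[v] = g @ pmats[v]
            logU[v] = lg
        return G, logG, U, logU

    # -- likelihood -------------------------------------------------------
    def loglik(self, blens) -> float:
        pmats = {
            v: self.transition_matrix(blens[v])
            for v in self.tree.branch_nodes
        }
        _, logS, _, f_raw = self._forward(blens, pmats)
        if np.any(f_raw <= 0):
            return -np.inf
        return float(np.dot(self.counts, np.log(f_raw) + logS[self.tree.root]))

    def loglik_and_grad(self, blens):
        tree = self.tree
        pmats = {v: self.transition_matrix(blens[v]) for v in tree.branch_nodes}
        D, logS, msg, f_raw = self._forward(blens, pmats)
        if np.any(f_raw <= 0):
            return -np.inf, np.zeros(len(blens))
        lnl = float(np.dot(self.counts, np.log(f_raw) + logS[tree.root]))
        G, logG, _, _ = self._backward(D, logS, msg, pmats)
        grad = np.zeros(len(blens))
        s_root = logS[tree.root]
        for v in tree.branch_nodes:
            qp = self.q @ pmats[v]
            if tree.children[v]:
                inner = ((G[v] @ qp) * D[v]).sum(axis=1)
            else:
                inner = self._tip_inner(v, G[v], qp)
            coef = self.counts * np.exp(logG[v] + logS[v] - s_root) / f_raw
            grad[v] = float(np.dot(coef, inner))
        return lnl, grad

    # -- expected counts --------------------------------------------------
    def expected_counts(self, blens):
        """Posterior expected substitution counts and category
        opportunities per branch.

        Returns (counts, opportunity): dicts node -> length-8 arrays; the
        counts of the eight categories sum to the total expected number
        of substitutions on the branch.
        """
        tree = self.tree
        pmats = {v: self.transition_matrix(blens[v]) for v in tree.branch_nodes}
        D, logS, msg, f_raw = self._forward(blens, pmats)
        if np.any(f_raw <= 0):
            raise FitError("zero-likelihood site pattern under fitted model")
        G, logG, U, logU = self._backward(D, logS, msg, pmats)
        s_root = logS[tree.root]
        cat = cd.category_matrix()
        q_cat = np.stack([np.where(cat == k, self.q, 0.0) for k in range(8)])
        a_cat = np.matmul(np.matmul(self.vr, q_cat), self.vl)   # (8, 61, 61)

        counts: dict[int, np.ndarray] = {}
        opportunity: dict[int, np.ndarray] = {}
        post_cache: dict[int, np.ndarray] = {}
        for v in tree.branch_nodes:
            j = self._integral_weights(blens[v])
            coef = self.counts * np.exp(logG[v] + logS[v] - s_root) / f_raw
            # all eight category integrals in one batched product
            m_all = np.matmul(np.matmul(self.vl, a_cat * j), self.vr)
            flat = m_all.transpose(1, 0, 2).reshape(_N, 8 * _N)
            gm = (G[v] @ flat).reshape(-1, 8, _N)
            if tree.children[v]:
                inner = (gm * D[v][:, None, :]).sum(axis=2)   # (npat, 8)
            else:
                codes = self.tip_codes[v]
                obs = codes >= 0
                inner = np.empty((codes.shape[0], 8))
                if obs.any():
                    inner[obs] = np.take_along_axis(
                        gm[obs], codes[obs][:, None, None].repeat(8, axis=1)
                        .astype(np.intp), axis=2,
                    )[:, :, 0]
                if (~obs).any():
                    inner[~obs] = gm[~obs].sum(axis=2)
            counts[v] = np.maximum(coef @ inner, 0.0)
            p = tree.parent[v]
            if p not in post_cache:
                post = U[p] * D[p]
                tot = post.sum(axis=1, keepdims=True)
                tot[tot == 0] = 1.0
                post_cache[p] = post / tot
            opportunity[v] = self.counts @ (post_cache[p] @ _OPP)
        return counts, opportunity


@dataclass
class GeneFit:
    """Fitted model for one alignment on the pruned tree."""

    tree: phylo.TreeIndex
    branch_lengths: np.ndarray
    kappa: float
    omega: float
    loglik: float
    pi: np.ndarray
    n_codons: int
    converged: bool
    engine: _Engine = field(repr=False)


def _init_branch_lengths(engine: _Engine) -> np.ndarray:
    """Pairwise-distance heuristic: seed every branch with the mean
    pairwise codon mismatch fraction spread over a typical path depth."""
    pat, cnt = engine.patterns, engine.counts
    ntips = pat.shape[1]
    diffs = []
    for a in range(ntips):
        for b in range(a + 1, ntips):
            ok = (pat[:, a] >= 0) & (pat[:, b] >= 0)
            if cnt[ok].sum() > 0:
                d = np.dot(cnt[ok], pat[ok, a] != pat[ok, b]) / cnt[ok].sum()
                diffs.append(d)
    mean_diff = float(np.mean(diffs)) if diffs else 0.05
    init = max(mean_diff / 4.0, 1e-3)
    blens = np.full(engine.tree.n_nodes, init)
    blens[engine.tree.root] = 0.0
    return blens


def fit_branch_lengths(
    alignment: dict[str, str],
    tree: dendropy.Tree | str,
    *,
    min_sequences: int = 3,
    kappa0: float = 2.0,
    omega0: float = 0.2,
    tol: float = 1e-6,
    max_rounds: int = 2,
    max_branch_length: float = 20.0,
) -> GeneFit:
    """Maximum-likelihood branch lengths, kappa, and omega under
    YN98(F3X4) with empirical frequencies, on the tree pruned to the
    species present in the alignment.

    An alignment with no variable site returns all branch lengths exactly
    zero (the log-likelihood is flat in the lengths at zero).
    """
    if isinstance(tree, str):
        tree = phylo.read_tree(tree)
    species = [t.taxon.label for t in tree.leaf_node_iter()
               if t.taxon.label in alignment]
    if len(species) < min_sequences:
        raise FitError(
            f"only {len(species)} of the alignment's sequences are on the "
            f"tree (need >= {min_sequences})"
        )
    pruned = phylo.prune_to_species(tree, species)
    index = phylo.index_tree(pruned)
    engine = _Engine(index, {s: alignment[s] for s in species})

    if not engine.has_variation:
        blens = np.zeros(index.n_nodes)
        engine.set_model(kappa0, omega0)
        lnl = engine.loglik(blens)
        return GeneFit(index, blens, kappa0, omega0, lnl, engine.pi3x4,
                       engine.n_sites, True, engine)

    branch_nodes = index.branch_nodes
    blens = _init_branch_lengths(engine)
    kappa, omega = kappa0, omega0
    engine.set_model(kappa, omega)
    prev = engine.loglik(blens)
    if not np.isfinite(prev):
        raise FitError("non-finite likelihood at initialization")
    converged = False
    for round_no in range(max_rounds):
        # branch lengths with analytic gradient, model fixed
        def nll(x):
            b = blens.copy()
            b[branch_nodes] = x
            lnl, grad = engine.loglik_and_grad(b)
            return -lnl, -grad[branch_nodes]

        res = optimize.minimize(
            nll,
            blens[branch_nodes],
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, max_branch_length)] * len(branch_nodes),
            options={"maxiter": 200, "ftol": 1e-10},
        )
        blens[branch_nodes] = res.x

        # kappa / omega with branch lengths fixed
        def nll_ko(logko):
            engine.set_model(np.exp(logko[0]), np.exp(logko[1]))
            return -engine.loglik(blens)

        res2 = optimize.minimize(
            nll_ko,
            np.log([kappa, omega]),
            method="Nelder-Mead",
            bounds=[(np.log(0.05), np.log(100.0)),
                    (np.log(1e-4), np.log(20.0))],
            options={
                "maxiter": 40 if round_no == 0 else 20,
                "fatol": 1e-8,
                "xatol": 1e-3,
            },
        )
        kappa, omega = np.exp(res2.x)
        engine.set_model(kappa, omega)
        lnl = engine.loglik(blens)
        if lnl - prev < tol:
            converged = True
            prev = max(lnl, prev)
            break
        prev = lnl
    if prev < -1e300 or not np.isfinite(prev):
        raise FitError("optimizer produced a non-finite likelihood")
    return GeneFit(index, blens, float(kappa), float(omega), float(prev),
                   engine.pi3x4, engine.n_sites, converged, engine)


def map_substitutions(fit: GeneFit) -> pd.DataFrame:
    """Per-branch, per-category substitution rates from the fitted model.

    Rows are branches (indexed by the name of the child node); columns are
    the eight category labels.  The returned frame carries the raw
    expected counts and opportunities in ``attrs['counts']`` and
    ``attrs['opportunity']`` (same shape).
    """
    engine = fit.engine
    engine.set_model(fit.kappa, fit.omega)
    counts, opportunity = engine.expected_counts(fit.branch_lengths)
    tree = fit.tree
    names = [tree.names[v] for v in tree.branch_nodes]
    cmat = np.array([counts[v] for v in tree.branch_nodes])
    omat = np.array([opportunity[v] for v in tree.branch_nodes])
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = np.where(omat > 0, cmat / np.maximum(omat, 1e-300), 0.0)
    df = pd.DataFrame(rates, index=names, columns=list(cd.CATEGORY_LABELS))
    df.attrs["counts"] = pd.DataFrame(cmat, index=names,
                                      columns=list(cd.CATEGORY_LABELS))
    df.attrs["opportunity"] = pd.DataFrame(omat, index=names,
                                           columns=list(cd.CATEGORY_LABELS))
    return df


def focal_rates(
    branch_rates: pd.DataFrame,
    tree: phylo.TreeIndex,
    focal_species: tuple[str, ...] = phylo.FOCAL_SPECIES,
    focal_node: str = "Muridae",
) -> pd.DataFrame:
    """Sum branch rates along the path from the focal ancestral node to
    each focal tip.  Focal species absent from the pruned tree get NaN."""
    try:
        anc = tree.find_node(focal_node)
    except KeyError:
        anc = phylo.muridae_node(tree, focal_species)
    rows = {}
    for sp in focal_species:
        if sp not in tree.tip_index:
            rows[sp] = pd.Series(np.nan, index=branch_rates.columns)
            continue
        path = tree.path_to_ancestor(sp, anc)
        names = [tree.names[v] for v in path]
        rows[sp] = branch_rates.loc[names].sum(axis=0)
    return pd.DataFrame(rows).T


def estimate_rates(
    alignments: dict[str, dict[str, str]],
    tree_newick: str,
    focal_species: tuple[str, ...] = phylo.FOCAL_SPECIES,
    focal_node: str = "Muridae",
    progress: bool = False,
) -> pd.DataFrame:
    """Run fit + mapping + focal-path summation for every gene.

    Returns a long table with one row per gene x focal species carrying
    the eight category rates, GC statistics of that species' sequence,
    and the fitted kappa/omega.  Genes that cannot be fitted are skipped
    and recorded in ``attrs['failures']``.
    """
    tree = phylo.read_tree(tree_newick)
    rows = []
    failures = {}
    items = sorted(alignments.items())
    for gid, aln in items:
        try:
            fit = fit_branch_lengths(aln, tree)
            branch = map_substitutions(fit)
            focal = focal_rates(branch, fit.tree, focal_species, focal_node)
        except (FitError, cd.CodonError, ValueError) as exc:
            failures[gid] = str(exc)
            continue
        for sp in focal_species:
            rec = {"gene": gid, "species": sp}
            rec.update(focal.loc[sp].to_dict())
            if sp in aln:
                try:
                    gc = cd.gc_content(aln[sp].replace("-", ""))
                    rec.update({"gc": gc.gc, "gc12": gc.gc12, "gc3": gc.gc3})
                except cd.CodonError:
                    rec.update({"gc": np.nan, "gc12": np.nan, "gc3": np.nan})
            else:
                rec.update({"gc": np.nan, "gc12": np.nan, "gc3": np.nan})
            rec["kappa"] = fit.kappa
            rec["omega"] = fit.omega
            rows.append(rec)
    df = pd.DataFrame(rows)
    df.attrs["failures"] = failures
    return df


def write_rates(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_rates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
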