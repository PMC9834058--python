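"""Codon substitution models: rate matrices, transition probabilities,
frequency and rate-variation estimation.

All models are time-reversible Markov processes on the 61 sense codons.
The generator ``Q`` is built from either empirical exchangeabilities
(``s_ij``, symmetric) or mechanistic parameters (MG/GY: only
single-nucleotide-change codon pairs exchange, with the non-synonymous /
synonymous rate ratio ``omega`` and, for GY, the transition / transversion
ratio ``kappa``), combined with equilibrium codon frequencies ``pi``.  ``Q``
is normalised so that the expected number of codon substitutions per site
per unit time at equilibrium is one, i.e. sum_{i != j} pi_i q_ij = 1, and
its diagonal completes each row to zero.  Transition probabilities are
P(t, r) = expm(Q t r) with the per-site rate multiplier ``r`` from the
among-site rate-variation (ASRV) model; reversibility lets us use a single
symmetric eigendecomposition instead of repeated matrix exponentials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .genetic_code import NUCLEOTIDES, UNIVERSAL_CODE, GeneticCode
from .phylo_io import CodonAlignment, MISSING, RootedTree

_FAMILIES = ("empirical", "MG", "GY")


@dataclass
class CodonModel:
    family: str
    pi: np.ndarray                 # (61,) equilibrium frequencies, sum 1
    Q: np.ndarray                  # (61, 61) normalised generator
    omega: float | None = None
    kappa: float | None = None
    s: np.ndarray | None = None    # exchangeabilities (empirical family)
    code: GeneticCode = field(default_factory=lambda: UNIVERSAL_CODE, repr=False)
    # eigendecomposition Q = U diag(eigvals) V, from the symmetrised form
    eigvals: np.ndarray = field(default=None, repr=False)
    U: np.ndarray = field(default=None, repr=False)
    V: np.ndarray = field(default=None, repr=False)

    def transition_factors(self, t: float, rates: np.ndarray) -> np.ndarray:
        """exp(eigvals * t * r_l) for each site: shape (L, 61)."""
        return np.exp(np.multiply.outer(np.asarray(rates) * t, self.eigvals))


@dataclass
class SiteRates:
    """Per-site rate multipliers r_l with mean approximately 1."""

    rates: np.ndarray
    n_categories: int
    alpha: float | None = None

    @classmethod
    def uniform(cls, n_sites: int) -> "SiteRates":
        return cls(np.ones(n_sites), 1, None)


def _mechanistic_exchangeabilities(
    family: str, omega: float, kappa: float, code: GeneticCode
) -> np.ndarray:
    h = code.single_nt_mask().astype(float)
    syn = code.synonymous_mask()
    h[~syn] *= omega
    if family == "GY":
        h[code.transition_mask()] *= kappa
    return h


def build_rate_matrix(
    family: str,
    pi: np.ndarray,
    omega: float | None = None,
    kappa: float | None = None,
    s: np.ndarray | None = None,
    code: GeneticCode = UNIVERSAL_CODE,
) -> CodonModel:
    """Build a normalised codon rate matrix.

    ``family`` is one of ``empirical`` (requires symmetric ``s``), ``MG``
    (requires ``omega``) or ``GY`` (requires ``omega`` and ``kappa``).
    """
    if family not in _FAMILIES:
        raise ValueError(f"unknown model family {family!r}")
    pi = np.asarray(pi, dtype=float).copy()
    if pi.shape != (code.n_codons,):
        raise ValueError(f"pi must have {code.n_codons} entries")
    if (pi < 0).any():
        raise ValueError("pi has negative entries")
    if (pi == 0).any():
        # keep Q irreducible: zero-frequency codons get a pseudo-frequency
        pi[pi == 0] = 1e-9
    pi = pi / pi.sum()

    if family == "empirical":
        if s is None:
            raise ValueError("empirical family requires exchangeabilities s")
        s = np.asarray(s, dtype=float)
        if not np.allclose(s, s.T, atol=1e-12 * max(1.0, np.abs(s).max())):
            raise ValueError("exchangeability matrix s must be symmetric")
        h = s.copy()
        if omega is not None:
            h = h.copy()
            h[~code.synonymous_mask()] *= omega
    else:
        if omega is None:
            raise ValueError(f"{family} family requires omega")
        kap = 1.0 if family == "MG" else kappa
        if family == "GY" and kappa is None:
            raise ValueError("GY family requires kappa")
        h = _mechanistic_exchangeabilities(family, float(omega), float(kap), code)

    Q = h * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    scale = float(pi @ Q.sum(axis=1))
    if scale <= 0:
        raise ValueError("degenerate rate matrix: zero total rate")
    Q = Q / scale
    np.fill_diagonal(Q, -Q.sum(axis=1))

    model = CodonModel(
        family=family, pi=pi, Q=Q, omega=omega, kappa=kappa,
        s=s if family == "empirical" else None, code=code,
    )
    _attach_eigen(model)
    return model


def _attach_eigen(model: CodonModel) -> None:
    """Eigendecompose Q through its symmetrised form when the model is
    reversible; otherwise leave the eigen fields unset and let
    ``transition_matrix`` fall back to scaling-and-squaring."""
    flux = model.pi[:, None] * model.Q
    if np.abs(flux - flux.T).max() > 1e-10 * max(np.abs(flux).max(), 1e-30):
        model.eigvals = None
        model.U = model.V = None
        return
    sq = np.sqrt(model.pi)
    A = (sq[:, None] * model.Q) / sq[None, :]
    A = 0.5 * (A + A.T)  # symmetrise away rounding noise
    w, R = np.linalg.eigh(A)
    model.eigvals = w
    model.U = R / sq[:, None]
    model.V = R.T * sq[None, :]


def transition_matrix(model: CodonModel, t: float, r: float = 1.0) -> np.ndarray:
    """P(t, r) = expm(Q t r); rows sum to 1, tiny negative entries clipped."""
    if not np.isfinite(t):
        raise ValueError("branch length t must be finite")
    if t < 0:
        raise ValueError("branch length t must be non-negative")
    if r <= 0:
        raise ValueError("site rate r must be positive")
    if model.eigvals is None:  # non-reversible generator
        from scipy.linalg import expm

        P = expm(model.Q * (t * r))
    else:
        e = np.exp(model.eigvals * (t * r))
        P = (model.U * e[None, :]) @ model.V
    np.clip(P, 0.0, None, out=P)
    return P


def estimate_frequencies(
    alignment: CodonAlignment, pseudocount: float = 1.0
) -> np.ndarray:
    """Codon frequencies proportional to observed counts, with additive
    pseudo-count smoothing (default 1 per codon, keeping Q irreducible)."""
    code = alignment.code
    states = alignment.codes[alignment.codes != MISSING]
    if states.size == 0:
        raise ValueError("alignment has no non-missing codons")
    counts = np.bincount(states, minlength=code.n_codons).astype(float)
    counts += pseudocount
    return counts / counts.sum()


def synthetic_exchangeabilities(
    code: GeneticCode = UNIVERSAL_CODE,
    kappa: float = 8.0,
    multi_hit: float = 0.02,
    syn_multi_hit: float = 0.6,
) -> np.ndarray:
    """Synthetic empirical-style codon exchangeability matrix.

    Not a published matrix: a deterministic stand-in with the structural
    signature of empirical codon models -- every codon pair exchanges, with
    multi-nucleotide changes discounted per extra changed position
    (``multi_hit`` for non-synonymous pairs, the much milder
    ``syn_multi_hit`` for synonymous ones) and transitions favoured over
    transversions by ``kappa`` at each changed position.  Intended as the
    default benchmark model, since purely single-nucleotide-change
    mechanistic models cannot represent the multi-hit substitutions that
    empirical matrices assign appreciable rates to.  The defaults mirror
    two well-documented features of empirical codon matrices rather than a
    nucleotide-level mutation process: a very strong effective enrichment
    of (synonymous) transitions, and multi-nucleotide exchangeabilities
    that are large mainly between synonymous or conservative codon pairs
    (e.g. within the Leu/Ser/Arg six-codon groups).
    """
    arr = np.array([[NUCLEOTIDES.index(n) for n in c] for c in code.codons])
    purine = np.isin(arr, [0, 2])
    diff = arr[:, None, :] != arr[None, :, :]
    ts = diff & (purine[:, None, :] == purine[None, :, :])
    ndiff = diff.sum(axis=2)
    mh = np.where(code.synonymous_mask(), syn_multi_hit, multi_hit)
    s = (kappa ** ts.sum(axis=2)) * mh ** np.maximum(ndiff - 1, 0)
    s[ndiff == 0] = 0.0
    return s


def read_exchangeabilities(text: str, code: GeneticCode = UNIVERSAL_CODE) -> np.ndarray:
    """Read a whitespace-delimited lower-triangular 61x61 exchangeability
    matrix preceded by a 61-codon order header; returns the full symmetric
    matrix in the canonical codon order."""
    tokens_lines = [ln.split() for ln in text.splitlines() if ln.strip()]
    header = tokens_lines[0]
    if len(header) != code.n_codons:
        raise ValueError("exchangeability header must list 61 codons")
    try:
        order = [code.codon_index[c.upper()] for c in header]
    except KeyError as exc:
        raise ValueError(f"unknown codon in header: {exc}") from exc
    vals = [float(v) for row in tokens_lines[1:] for v in row]
    n = code.n_codons
    if len(vals) != n * (n - 1) // 2:
        raise ValueError(
            f"expected {n * (n - 1) // 2} lower-triangular values, got {len(vals)}"
        )
    s_perm = np.zeros((n, n))
    k = 0
    for i in range(1, n):
        for j in range(i):
            s_perm[i, j] = s_perm[j, i] = vals[k]
            k += 1
    s = np.zeros((n, n))
    idx = np.asarray(order)
    s[np.ix_(idx, idx)] = s_perm
    return s


# -- among-site rate variation ---------------------------------------------


def discrete_gamma_rates(alpha: float, n_categories: int) -> np.ndarray:
    """Mean rates of ``n_categories`` equal-probability bins of a unit-mean
    gamma distribution (shape ``alpha``)."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    k = n_categories
    edges = gamma_dist.ppf(np.arange(1, k) / k, alpha, scale=1.0 / alpha)
    bounds = np.concatenate([[0.0], edges * alpha, [np.inf]])
    cum = gammainc(alpha + 1.0, bounds[1:])
    cum_lo = gammainc(alpha + 1.0, bounds[:-1])
    rates = k * (cum - cum_lo)
    return rates / rates.mean() * 1.0  # guard rounding; mean is already ~1


def estimate_site_rates(
    tree: RootedTree,
    alignment: CodonAlignment,
    model: CodonModel,
    n_categories: int = 4,
) -> SiteRates:
    """Fit a discrete-gamma ASRV model by maximum likelihood and return
    per-site posterior-mean rate multipliers.

    With one category, or with fewer than two sites (rate variation is then
    unidentifiable and the fit falls back with a warning), all rates are 1.
    """
    L = alignment.n_sites
    if n_categories < 1:
        raise ValueError("n_categories must be >= 1")
    if n_categories == 1:
        return SiteRates.uniform(L)
    if L < 2:
        warnings.warn("fewer than 2 sites: ASRV unidentifiable, using r_l = 1")
        return SiteRates.uniform(L)

    from ._pruning import PruningEngine

    engine = PruningEngine(tree, alignment)

    def site_mix_loglik(alpha: float) -> tuple[float, np.ndarray, np.ndarray]:
        cats = discrete_gamma_rates(alpha, n_categories)
        per_cat = np.stack(
            [engine.site_log_likelihoods(model, np.full(L, rc)) for rc in cats]
        )  # (ncat, L)
        m = per_cat.max(axis=0)
        lik = np.exp(per_cat - m[None, :])
        site_ll = m + np.log(lik.mean(axis=0))
        post = lik / lik.sum(axis=0, keepdims=True)
        return float(site_ll.sum()), post, cats

    res = minimize_scalar(
        lambda la: -site_mix_loglik(float(np.exp(la)))[0],
        bounds=(np.log(0.05), np.log(50.0)),
        method="bounded",
        options={"xatol": 0.02},
    )
    alpha = float(np.exp(res.x))
    _, post, cats = site_mix_loglik(alpha)
    rates = cats @ post  # posterior-mean rate per site
    return SiteRates(rates, n_categories, alpha)


def estimate_omega(
    tree: RootedTree,
    alignment: CodonAlignment,
    pi: np.ndarray,
    family: str = "MG",
    kappa: float | None = None,
    s: np.ndarray | None = None,
    site_rates: SiteRates | None = None,
    bounds: tuple[float, float] = (0.01, 5.0),
    code: GeneticCode = UNIVERSAL_CODE,
) -> float:
    """Maximum-likelihood estimate of omega (single ratio across sites)."""
    from ._pruning import PruningEngine

    engine = PruningEngine(tree, alignment)
    rates = (
        site_rates.rates if site_rates is not None
        else np.ones(alignment.n_sites)
    )

    def negll(logw: float) -> float:
        model = build_rate_matrix(
            family, pi, omega=float(np.exp(logw)), kappa=kappa, s=s, code=code
        )
        return -float(engine.site_log_likelihoods(model, rates).sum())

    res = minimize_scalar(
        negll,
        bounds=(np.log(bounds[0]), np.log(bounds[1])),
        method="bounded",
        options={"xatol": 0.02},
    )
    return float(np.exp(res.x))
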