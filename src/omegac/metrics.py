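"""Observed and expected combinatorial substitutions and the derived rates.

A branch combination of order K accumulates, per codon site, the product
over its K branches of branch-wise substitution probabilities, under one of
five categories:

* ``any2any`` -- paired substitutions: each branch substitutes, any states;
* ``any2spe`` -- convergence: all branches arrive at the same derived state;
* ``spe2spe`` -- concordant convergence: shared ancestral and derived state;
* ``any2dif`` = any2any - any2spe (double divergence);
* ``dif2spe`` = any2spe - spe2spe (discordant convergence).

States are amino acids in the non-synonymous view (``N``) and codons within
an amino-acid group in the synonymous view (``S``).  Summing the per-site
probabilities over sites gives O_C (from observed tensors) or E_C (from
model-expected tensors); their ratios give dN_C = O^N/E^N and
dS_C = O^S/E^S, and the convergence rate ratio omega_C = dN_C / dS_C.
dS_C is optionally rescaled onto the dN_C distribution range through its
empirical quantile rank (a saturation correction, applicable only when the
combinations at that K were enumerated exhaustively).  C/D is the legacy
convergent-to-divergent count ratio O^{N,any2spe} / O^{N,any2dif}.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ancestral import AncestralPosteriors
from .codon_model import CodonModel, SiteRates
from .genetic_code import MAX_SYNONYMS
from .phylo_io import RootedTree
from .tensors import RescaledBranchLengths, SubstitutionTensors

CATEGORIES = ("any2any", "any2spe", "any2dif", "dif2spe", "spe2spe")
#: categories computed directly; the other two follow by subtraction
_DIRECT = ("any2any", "any2spe", "spe2spe")


# ---------------------------------------------------------------------------
# expected substitution tensors


def expected_substitution_tensors(
    posteriors: AncestralPosteriors,
    tree: RootedTree,
    model: CodonModel,
    rescaled: RescaledBranchLengths,
    site_rates: SiteRates | None = None,
    missing: np.ndarray | None = None,
) -> SubstitutionTensors:
    """Model-expected substitution tensors.

    For branch *b* and site *l*, the expected substitution distribution is
    the ancestral (parent-node) marginal posterior times the codon
    transition matrix, using the rescaled non-synonymous branch length for
    the A^N view and the synonymous one for A^S, each modulated by the
    per-site rate r_l.  The aggregation to amino-acid (and within-group
    codon) resolution is carried out through the model's eigendecomposition
    so the 61 x 61 transition matrices are never materialised per site.
    """
    code = posteriors.code
    branches = tree.branches
    parents = tree.parent[branches]
    B = len(branches)
    L = posteriors.n_sites
    rates = site_rates.rates if site_rates is not None else np.ones(L)
    if missing is None:
        missing = posteriors.missing[parents] | posteriors.missing[branches]

    U, V, eig = model.U, model.V, model.eigvals
    ind = code.aa_indicator()
    VC = V @ ind  # (61, 20)
    nA = code.n_amino_acids
    eyeA = np.eye(nA, dtype=bool)

    P = posteriors.probs[parents]  # (B, L, 61) ancestral marginals
    # Rescaled branch lengths are view-specific substitution counts, but Q
    # mixes synonymous and non-synonymous flux and the observable
    # (endpoint-difference) mass saturates in time.  For each branch and
    # view, solve for the model time at which the expected substitution
    # mass, weighted by the branch's ancestral posteriors, equals the
    # observed rescaled total -- exact conservation; at small t this
    # reduces to dividing the length by the view's equilibrium flux share.
    t_n, t_s = _invert_view_times(model, P, rescaled, code)

    AN = np.empty((B, L, nA, nA))
    AS = np.zeros((B, L, nA, MAX_SYNONYMS, MAX_SYNONYMS))
    uniform = np.allclose(rates, rates[0])
    if uniform:
        # one transition matrix per branch and view; aggregation is cheap
        r0 = float(rates[0])
        fN = np.exp(np.multiply.outer(t_n * r0, eig))   # (B, 61)
        fS = np.exp(np.multiply.outer(t_s * r0, eig))
        PN = (U[None, :, :] * fN[:, None, :]) @ V       # (B, 61, 61)
        PS = (U[None, :, :] * fS[:, None, :]) @ V
        PNC = PN @ ind                                   # (B, 61, 20)
        for g, idx in enumerate(code.aa_groups):
            k = len(idx)
            AN[:, :, g, :] = np.einsum(
                "bli,bic->blc", P[:, :, idx], PNC[:, idx, :]
            )
            AS[:, :, g, :k, :k] = np.einsum(
                "bli,bij->blij", P[:, :, idx], PS[:, idx[:, None], idx[None, :]]
            )
    else:
        # per-site rates: route through the eigenbasis instead of forming
        # per-site transition matrices
        eN = np.exp(eig[None, None, :] * (t_n[:, None] * rates[None, :])[:, :, None])
        eS = np.exp(eig[None, None, :] * (t_s[:, None] * rates[None, :])[:, :, None])
        for g, idx in enumerate(code.aa_groups):
            k = len(idx)
            GPg = P[:, :, idx] @ U[idx, :]          # (B, L, 61)
            AN[:, :, g, :] = (GPg * eN) @ VC        # expected aa-level row g
            T = (P[:, :, idx, None] * U[None, None, idx, :]) * eS[:, :, None, :]
            AS[:, :, g, :k, :k] = T @ V[:, idx]
    AN[..., eyeA] = 0.0
    np.clip(AN, 0.0, None, out=AN)
    for g, idx in enumerate(code.aa_groups):
        k = len(idx)
        AS[:, :, g, np.arange(k), np.arange(k)] = 0.0
    np.clip(AS, 0.0, None, out=AS)

    AN[missing] = 0.0
    AS[missing] = 0.0
    return SubstitutionTensors(AN, AS, missing.copy(), branches, code)


_TAU_GRID = np.concatenate([[0.0], np.geomspace(1e-4, 30.0, 160)])


def _invert_view_times(model, P, rescaled, code):
    """Per-branch model times for the N and S views.

    On a monotone time grid, precompute the model's expected per-site
    substitution mass (non-synonymous and synonymous endpoint-difference
    mass of P(tau)) for every ancestral state, weight it by each branch's
    summed ancestral posteriors, and invert by interpolation so that the
    expected tensors integrate to the branch's observed rescaled length.
    Branches whose observed mass exceeds the saturation asymptote are
    capped at the top of the grid.
    """
    syn = code.synonymous_mask()
    nonsyn_off = ~syn
    syn_off = syn & ~np.eye(code.n_codons, dtype=bool)
    K = len(_TAU_GRID)
    nmN = np.empty((K, code.n_codons))
    nmS = np.empty((K, code.n_codons))
    for k, tau in enumerate(_TAU_GRID):
        e = np.exp(model.eigvals * tau)
        Pt = (model.U * e[None, :]) @ model.V
        np.clip(Pt, 0.0, None, out=Pt)
        nmN[k] = (Pt * nonsyn_off).sum(axis=1)
        nmS[k] = (Pt * syn_off).sum(axis=1)
    W = P.sum(axis=1)  # (B, 61) summed ancestral posteriors per branch
    eff = np.maximum(rescaled.effective_sites.astype(float), 1.0)
    FN = (W @ nmN.T) / eff[:, None]   # (B, K) expected mass per site
    FS = (W @ nmS.T) / eff[:, None]
    B = W.shape[0]
    t_n = np.empty(B)
    t_s = np.empty(B)
    for b in range(B):
        fn = np.maximum.accumulate(FN[b])
        fs = np.maximum.accumulate(FS[b])
        t_n[b] = np.interp(rescaled.t_N[b], fn, _TAU_GRID)
        t_s[b] = np.interp(rescaled.t_S[b], fs, _TAU_GRID)
    return t_n, t_s


# ---------------------------------------------------------------------------
# combinatorial totals


def _per_site(
    tensors: SubstitutionTensors, idx: Sequence[int], category: str, view: str
) -> np.ndarray:
    if view == "N":
        if category == "any2any":
            return np.prod(tensors.total_N()[idx], axis=0)
        if category == "any2spe":
            return np.prod(tensors.derived_N()[idx], axis=0).sum(axis=-1)
        if category == "spe2spe":
            return np.prod(tensors.AN[idx], axis=0).sum(axis=(-2, -1))
    elif view == "S":
        if category == "any2any":
            return np.prod(tensors.total_S()[idx], axis=0).sum(axis=-1)
        if category == "any2spe":
            return np.prod(tensors.derived_S()[idx], axis=0).sum(axis=(-2, -1))
        if category == "spe2spe":
            return np.prod(tensors.AS[idx], axis=0).sum(axis=(-3, -2, -1))
    raise ValueError(f"unknown category/view: {category!r}/{view!r}")


def combinatorial_per_site(
    tensors: SubstitutionTensors,
    branch_ids: Sequence[int],
    category: str,
    view: str,
) -> np.ndarray:
    """Per-site combinatorial substitution probabilities P_l(S_C)."""
    if len(branch_ids) < 2:
        raise ValueError("a branch combination needs at least two branches")
    if len(set(branch_ids)) != len(branch_ids):
        raise ValueError("duplicate branch ids in combination")
    idx = [tensors.branch_index(b) for b in branch_ids]
    if category in _DIRECT:
        return _per_site(tensors, idx, category, view)
    if category == "any2dif":
        return _per_site(tensors, idx, "any2any", view) - _per_site(
            tensors, idx, "any2spe", view
        )
    if category == "dif2spe":
        return _per_site(tensors, idx, "any2spe", view) - _per_site(
            tensors, idx, "spe2spe", view
        )
    raise ValueError(f"unknown category {category!r}")


def observed_combinatorial(
    tensors: SubstitutionTensors,
    branch_ids: Sequence[int],
    category: str,
    view: str,
) -> float:
    """O_C: combinatorial substitution probability summed over sites."""
    return float(combinatorial_per_site(tensors, branch_ids, category, view).sum())


#: E_C is obtained by the same accumulation applied to expected tensors
expected_combinatorial = observed_combinatorial


def pairwise_totals(
    tensors: SubstitutionTensors, category: str, view: str
) -> np.ndarray:
    """(B, B) matrix of combination totals for every branch pair at once."""
    if category == "any2dif":
        return pairwise_totals(tensors, "any2any", view) - pairwise_totals(
            tensors, "any2spe", view
        )
    if category == "dif2spe":
        return pairwise_totals(tensors, "any2spe", view) - pairwise_totals(
            tensors, "spe2spe", view
        )
    if view == "N":
        arr = {
            "any2any": tensors.total_N(),
            "any2spe": tensors.derived_N(),
            "spe2spe": tensors.AN,
        }[category]
    else:
        arr = {
            "any2any": tensors.total_S(),
            "any2spe": tensors.derived_S(),
            "spe2spe": tensors.AS,
        }[category]
    flat = arr.reshape(arr.shape[0], -1)
    return flat @ flat.T


# ---------------------------------------------------------------------------
# rates, correction, ratios


def rates(o_n: float, e_n: float, o_s: float, e_s: float) -> tuple[float, float]:
    """(dN_C, uncorrected dS_C) = (O^N/E^N, O^S/E^S) with 0/0 -> NaN and
    O>0/E=0 -> +inf."""
    return _safe_ratio(o_n, e_n), _safe_ratio(o_s, e_s)


def _safe_ratio(o, e):
    o = np.asarray(o, dtype=float)
    e = np.asarray(e, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(e > 0, o / np.maximum(e, 1e-300), np.where(o > 0, np.inf, np.nan))
    return r if r.ndim else float(r)


@dataclass
class QuantileMap:
    """Empirical dN_C and dS_C distributions over the exhaustively
    enumerated combinations at one K (finite values only, sorted)."""

    dn_sorted: np.ndarray
    ds_sorted: np.ndarray

    @classmethod
    def from_rates(cls, dn: np.ndarray, ds: np.ndarray) -> "QuantileMap":
        dn = np.asarray(dn, dtype=float)
        ds = np.asarray(ds, dtype=float)
        return cls(np.sort(dn[np.isfinite(dn)]), np.sort(ds[np.isfinite(ds)]))

    @property
    def usable(self) -> bool:
        return len(self.dn_sorted) >= 2 and len(self.ds_sorted) >= 2


def correct_dsc(dn, ds, qmap: QuantileMap | None):
    """Saturation-corrected dS_C.

    Where dS_C < dN_C, dS_C is replaced by the quantile of the empirical
    dN_C distribution at dS_C's own quantile rank (linear interpolation
    between order statistics); otherwise it is returned unchanged.  Without
    a usable quantile map the uncorrected value is returned.
    """
    dn = np.asarray(dn, dtype=float)
    ds = np.asarray(ds, dtype=float)
    scalar = dn.ndim == 0
    dn, ds = np.atleast_1d(dn), np.atleast_1d(ds)
    out = ds.copy()
    if qmap is not None and qmap.usable:
        pos_s = np.linspace(0.0, 1.0, len(qmap.ds_sorted))
        pos_n = np.linspace(0.0, 1.0, len(qmap.dn_sorted))
        needs = np.isfinite(ds) & np.isfinite(dn) & (ds < dn)
        if needs.any():
            p = np.interp(ds[needs], qmap.ds_sorted, pos_s)
            out[needs] = np.interp(p, pos_n, qmap.dn_sorted)
    return float(out[0]) if scalar else out


def omega_c(dn, ds):
    """omega_C = dN_C / dS_C; dS_C = 0 with dN_C > 0 -> +inf, 0/0 -> NaN."""
    return _safe_ratio(dn, ds)


def c_over_d(o_n_any2spe, o_n_any2dif):
    """Legacy C/D metric: convergent over doubly-divergent non-synonymous
    totals; NaN when the divergence total is zero."""
    o_spe = np.asarray(o_n_any2spe, dtype=float)
    o_dif = np.asarray(o_n_any2dif, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(o_dif > 0, o_spe / np.maximum(o_dif, 1e-300), np.nan)
    return r if r.ndim else float(r)


# ---------------------------------------------------------------------------
# record assembly


def combination_record(
    obs: SubstitutionTensors,
    exp: SubstitutionTensors,
    branch_ids: Sequence[int],
    categories: Iterable[str] = CATEGORIES,
) -> dict:
    """All per-category quantities for one branch combination (dS_C here is
    uncorrected; the quantile correction needs the exhaustive K-level
    distributions and is applied table-wide)."""
    branch_ids = sorted(int(b) for b in branch_ids)
    idx = [obs.branch_index(b) for b in branch_ids]
    rec: dict = {"branches": tuple(branch_ids), "K": len(branch_ids)}
    rec["effective_sites"] = int((~obs.missing[idx]).all(axis=0).sum())
    for cat in categories:
        rec[f"OCN_{cat}"] = observed_combinatorial(obs, branch_ids, cat, "N")
        rec[f"OCS_{cat}"] = observed_combinatorial(obs, branch_ids, cat, "S")
        rec[f"ECN_{cat}"] = expected_combinatorial(exp, branch_ids, cat, "N")
        rec[f"ECS_{cat}"] = expected_combinatorial(exp, branch_ids, cat, "S")
        dn, ds = rates(
            rec[f"OCN_{cat}"], rec[f"ECN_{cat}"],
            rec[f"OCS_{cat}"], rec[f"ECS_{cat}"],
        )
        rec[f"dNC_{cat}"] = dn
        rec[f"dSC_{cat}"] = ds
        rec[f"omegaC_{cat}"] = omega_c(dn, ds)
    if "OCN_any2spe" in rec and "OCN_any2dif" in rec:
        rec["CD"] = c_over_d(rec["OCN_any2spe"], rec["OCN_any2dif"])
    return rec


def pair_table(
    obs: SubstitutionTensors,
    exp: SubstitutionTensors,
    pairs: np.ndarray,
    categories: Sequence[str] = CATEGORIES,
    correct: bool = True,
) -> pd.DataFrame:
    """Exhaustive K = 2 table over the given independent branch pairs.

    Vectorised over all pairs; when ``correct`` is set the dS_C quantile
    correction is applied per category using the table's own empirical
    distributions, and omega_C uses the corrected value (the uncorrected
    one is kept in ``dSC_<cat>_uncorrected``).
    """
    pairs = np.asarray(pairs, dtype=int)
    i1 = pairs[:, 0] - 1
    i2 = pairs[:, 1] - 1
    data: dict = {
        "branch1": pairs[:, 0],
        "branch2": pairs[:, 1],
        "K": 2,
        "effective_sites": (~(obs.missing[i1] | obs.missing[i2])).sum(axis=1),
    }
    need = set(categories)
    if "any2dif" in need:
        need |= {"any2any", "any2spe"}
    if "dif2spe" in need:
        need |= {"any2spe", "spe2spe"}
    mats: dict = {}
    for cat in sorted(need & set(_DIRECT)):
        for view in "NS":
            mats[("O", cat, view)] = pairwise_totals(obs, cat, view)[i1, i2]
            mats[("E", cat, view)] = pairwise_totals(exp, cat, view)[i1, i2]
    for kind in ("O", "E"):
        for view in "NS":
            if "any2dif" in categories:
                mats[(kind, "any2dif", view)] = (
                    mats[(kind, "any2any", view)] - mats[(kind, "any2spe", view)]
                )
            if "dif2spe" in categories:
                mats[(kind, "dif2spe", view)] = (
                    mats[(kind, "any2spe", view)] - mats[(kind, "spe2spe", view)]
                )
    for cat in categories:
        data[f"OCN_{cat}"] = mats[("O", cat, "N")]
        data[f"OCS_{cat}"] = mats[("O", cat, "S")]
        data[f"ECN_{cat}"] = mats[("E", cat, "N")]
        data[f"ECS_{cat}"] = mats[("E", cat, "S")]
        dn = _safe_ratio(data[f"OCN_{cat}"], data[f"ECN_{cat}"])
        ds = _safe_ratio(data[f"OCS_{cat}"], data[f"ECS_{cat}"])
        data[f"dNC_{cat}"] = dn
        data[f"dSC_{cat}_uncorrected"] = ds
        if correct:
            qmap = QuantileMap.from_rates(dn, ds)
            ds_c = correct_dsc(dn, ds, qmap)
        else:
            ds_c = ds
        data[f"dSC_{cat}"] = ds_c
        data[f"omegaC_{cat}"] = omega_c(dn, ds_c)
    if {"any2spe", "any2dif"} <= set(categories):
        data["CD"] = c_over_d(data["OCN_any2spe"], data["OCN_any2dif"])
    return pd.DataFrame(data)
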