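"""End-to-end analysis: tree + alignment -> per-combination convergence
metrics, and the scenario benchmark built on top of it.

``analyze`` runs the complete method: codon frequencies from the alignment
(+F), optional maximum-likelihood estimation of omega and of discrete-gamma
site rates, marginal ancestral reconstruction, substitution tensors with
branch-length rescaling, model-expected tensors, exhaustive K = 2 metrics
with the dS_C quantile correction, and (optionally) the higher-order
branch-and-bound search.

``run_scenario`` repeats simulation + analysis for one benchmark scenario
and reports the focal-pair metrics per replicate; ``benchmark`` summarises
all four scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ancestral import AncestralPosteriors, reconstruct
from .codon_model import (
    CodonModel,
    SiteRates,
    build_rate_matrix,
    estimate_frequencies,
    estimate_omega,
    estimate_site_rates,
)
from .metrics import CATEGORIES, expected_substitution_tensors, pair_table
from .phylo_io import CodonAlignment, RootedTree, check_labels
from .search import SearchConfig, branch_and_bound, enumerate_pairs
from .simulate import (
    SimulationScenario,
    apply_transfer,
    shuffle_tree_labels,
    simulate_convergent,
    simulate_neutral,
)
from .tensors import (
    RescaledBranchLengths,
    SubstitutionTensors,
    build_tensors,
    rescale_branch_lengths,
)

#: the categories needed for convergence rates and C/D (the benchmark set)
CONVERGENCE_CATEGORIES = ("any2any", "any2spe", "any2dif")


@dataclass
class AnalysisResult:
    pairs: pd.DataFrame
    rescaled: RescaledBranchLengths
    observed: SubstitutionTensors
    expected: SubstitutionTensors
    posteriors: AncestralPosteriors
    model: CodonModel
    site_rates: SiteRates
    higher_order: dict[int, pd.DataFrame] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)


def analyze(
    tree: RootedTree,
    alignment: CodonAlignment,
    model_family: str = "MG",
    omega: float | None = None,
    kappa: float | None = None,
    exchangeabilities: np.ndarray | None = None,
    n_rate_categories: int = 1,
    exclude_sisters: bool = True,
    categories=CATEGORIES,
    freq_pseudocount: float = 1.0,
    search: SearchConfig | None = None,
) -> AnalysisResult:
    """Run the full convergence analysis on one tree and alignment.

    ``omega = None`` triggers a maximum-likelihood estimate (mechanistic
    families only).  ``search`` switches on the higher-order
    branch-and-bound exploration.
    """
    check_labels(tree, alignment)
    pi = estimate_frequencies(alignment, pseudocount=freq_pseudocount)
    meta: dict = {"model_family": model_family}
    if omega is None and (
        model_family in ("MG", "GY") or exchangeabilities is not None
    ):
        omega = estimate_omega(
            tree, alignment, pi, family=model_family, kappa=kappa,
            s=exchangeabilities, code=alignment.code,
        )
    meta["omega"] = omega
    meta["kappa"] = kappa
    model = build_rate_matrix(
        model_family, pi, omega=omega, kappa=kappa, s=exchangeabilities,
        code=alignment.code,
    )
    site_rates = (
        estimate_site_rates(tree, alignment, model, n_rate_categories)
        if n_rate_categories > 1
        else SiteRates.uniform(alignment.n_sites)
    )
    meta["asrv_alpha"] = site_rates.alpha
    posteriors = reconstruct(tree, alignment, model, site_rates)
    observed = build_tensors(posteriors, tree)
    rescaled = rescale_branch_lengths(observed)
    expected = expected_substitution_tensors(
        posteriors, tree, model, rescaled, site_rates, missing=observed.missing
    )
    pairs = enumerate_pairs(tree, exclude_sisters=exclude_sisters)
    table = pair_table(observed, expected, pairs, categories=categories)
    higher: dict[int, pd.DataFrame] = {}
    if search is not None:
        higher = branch_and_bound(observed, expected, tree, search, categories)
        table = higher[2]
    return AnalysisResult(
        pairs=table,
        rescaled=rescaled,
        observed=observed,
        expected=expected,
        posteriors=posteriors,
        model=model,
        site_rates=site_rates,
        higher_order=higher,
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# scenario benchmark


FOCAL_METRICS = (
    "omegaC_any2spe",
    "dNC_any2spe",
    "dSC_any2spe",
    "dSC_any2spe_uncorrected",
    "OCN_any2spe",
    "OCS_any2spe",
    "CD",
)


def _focal_row(table: pd.DataFrame, focal: tuple[int, int]) -> pd.Series:
    b1, b2 = sorted(focal)
    row = table[(table.branch1 == b1) & (table.branch2 == b2)]
    if len(row) != 1:
        raise ValueError(
            f"focal pair {focal} absent from the pair table (excluded as "
            "non-independent?)"
        )
    return row.iloc[0]


def run_replicate(
    scenario: SimulationScenario, seed: int, n_rate_categories: int = 1
) -> dict:
    """One simulation + analysis replicate; returns the focal-pair metrics."""
    name = scenario.scenario
    rng = np.random.default_rng(seed)
    if name == "Convergent":
        aln, _states, tree, _truth = simulate_convergent(scenario, rng)
        analysis_tree = tree
    elif name in ("Neutral", "Transfer", "Random"):
        aln, _states, tree = simulate_neutral(scenario, rng)
        analysis_tree = tree
        if name == "Transfer":
            aln = apply_transfer(aln, *scenario.focal_tips)
        elif name == "Random":
            analysis_tree = shuffle_tree_labels(tree, rng)
            # keep the focal pair analysable: re-shuffle if it lands on
            # a sister pair under the randomised topology
            for _ in range(100):
                focal = scenario.focal_branches(analysis_tree)
                if not analysis_tree.are_sisters(*focal):
                    break
                analysis_tree = shuffle_tree_labels(tree, rng)
    else:
        raise ValueError(f"unknown scenario {name!r}")

    result = analyze(
        analysis_tree,
        aln,
        model_family=scenario.model_family,
        omega=None,
        kappa=scenario.kappa,
        exchangeabilities=scenario.exchangeabilities(),
        n_rate_categories=n_rate_categories,
        exclude_sisters=True,
        categories=CONVERGENCE_CATEGORIES,
    )
    focal = scenario.focal_branches(analysis_tree)
    row = _focal_row(result.pairs, focal)
    out = {"scenario": name, "seed": seed}
    for m in FOCAL_METRICS:
        out[m] = float(row[m])
    return out


def run_scenario(
    scenario_name: str,
    n_replicates: int,
    seed: int,
    scenario: SimulationScenario | None = None,
    **scenario_kwargs,
) -> pd.DataFrame:
    """Run ``n_replicates`` of one scenario; replicate seeds are spawned
    deterministically from ``seed``."""
    base = scenario or SimulationScenario(
        scenario=scenario_name, **scenario_kwargs
    )
    if base.scenario != scenario_name:
        raise ValueError("scenario name mismatch")
    root = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(n_replicates)]
    rows = [run_replicate(base, s) for s in child_seeds]
    return pd.DataFrame(rows)


def benchmark(
    n_replicates: int,
    seed: int,
    scenarios: tuple[str, ...] = ("Neutral", "Convergent", "Transfer", "Random"),
    **scenario_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scenario x metric benchmark.

    Returns (per-replicate table, summary).  The summary reports, per
    scenario and metric, the median, the Neutral 95th percentile of that
    metric, and the positive rate (fraction of replicates above the Neutral
    95th percentile) -- the scheme used to declare true/false positives.
    """
    frames = []
    for i, name in enumerate(scenarios):
        frames.append(
            run_scenario(name, n_replicates, seed + 7919 * i, **scenario_kwargs)
        )
    reps = pd.concat(frames, ignore_index=True)
    neutral = reps[reps.scenario == "Neutral"]
    rows = []
    metrics = ("omegaC_any2spe", "dNC_any2spe", "dSC_any2spe", "CD")
    for name in scenarios:
        sub = reps[reps.scenario == name]
        for m in metrics:
            vals = sub[m].to_numpy()
            finite = vals[np.isfinite(vals)]
            if len(neutral):
                ref = neutral[m].to_numpy()
                ref = ref[np.isfinite(ref)]
                q95 = float(np.percentile(ref, 95)) if len(ref) else np.nan
            else:
                q95 = np.nan
            pos = float(np.mean(vals > q95)) if np.isfinite(q95) else np.nan
            rows.append(
                {
                    "scenario": name,
                    "metric": m,
                    "median": float(np.median(finite)) if len(finite) else np.nan,
                    "neutral_q95": q95,
                    "positive_rate": pos,
                    "n": len(vals),
                }
            )
    return reps, pd.DataFrame(rows)
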