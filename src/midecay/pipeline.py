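"""End-to-end orchestration: per-individual analysis and study reports.

``run_individual`` pushes one corpus through the full stack — MI decay
curve, maximum dependency distance, three-family decay fit and AICc
ranking, transition point when the composite model wins, and (optionally)
the per-individual Markov null — on both the raw and the condensed stream.
``run_study`` aggregates individuals into the study-level tables:
descriptive statistics, max-distance and transition summaries with sample
(n-1) SDs, and the pooled-chain community experiment.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .corpus import Corpus, condense, summarize_corpus
from .decay import FAMILIES, DecayModelSelector, FitInfeasibleError
from .markov import MarkovChain, community_experiment, null_max_distance
from .mi import MIDecayEstimator
from .transition import compare_to_per_nut_length, transition_point

__all__ = ["RunConfig", "VariantResult", "IndividualResult", "StudyReport",
           "run_individual", "run_study", "mean_sd"]

logger = logging.getLogger("midecay")

MIN_CORPUS_LENGTH = 200  # entropy estimation is unreliable below this


@dataclass
class RunConfig:
    """Study-level parameters; defaults are the full-scale analysis values."""

    d_max: int = 100
    n_perm: int = 1000
    tie_threshold: float = 2.0
    condensed_variant: bool = True
    run_null: bool = True
    null_n_sims: int = 100
    community_n_sequences: int = 500
    community_sim_length: int = 1000
    drop_last_point: bool = False
    min_corpus_length: int = MIN_CORPUS_LENGTH
    seed: Optional[int] = None

    @classmethod
    def desk(cls, seed=None, **overrides) -> "RunConfig":
        """Reduced-scale preset for interactive / CI-speed runs."""
        base = dict(n_perm=200, null_n_sims=25, community_n_sequences=50, seed=seed)
        base.update(overrides)
        return cls(**base)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


@dataclass
class VariantResult:
    """One variant (raw or condensed) of a per-individual analysis."""

    variant: str
    curve: object
    max_distance: int
    censored: bool
    fits: dict
    fit_failures: dict
    comparison: object
    preferred_model: Optional[str]
    transition: object = None
    per_nut_row: Optional[dict] = None
    null: object = None


@dataclass
class IndividualResult:
    individual_id: str
    summary: object
    excluded: bool = False
    exclusion_reason: Optional[str] = None
    variants: dict = field(default_factory=dict)


def _analyse_variant(stream, variant, summary, config, seed) -> VariantResult:
    est = MIDecayEstimator(d_max=config.d_max, n_perm=config.n_perm, random_state=seed)
    est.fit(stream)
    x, y = est.curve_.fit_points(est.max_distance_, drop_last_point=config.drop_last_point)
    fits, failures, comparison, preferred = {}, {}, None, None
    try:
        sel = DecayModelSelector(tie_threshold=config.tie_threshold).fit(x, y)
        fits, failures = sel.fits_, sel.failures_
        comparison = sel.comparison_
        preferred = sel.best_family_
    except FitInfeasibleError as exc:
        failures = {fam: str(exc) for fam in FAMILIES}
        logger.warning("%s/%s: no decay model could be fitted (%s)", summary.individual_id, variant, exc)
    result = VariantResult(
        variant=variant,
        curve=est.curve_,
        max_distance=est.max_distance_,
        censored=est.censored_,
        fits=fits,
        fit_failures=failures,
        comparison=comparison,
        preferred_model=preferred,
    )
    if preferred == "composite":
        result.transition = transition_point(fits["composite"], est.max_distance_)
        result.per_nut_row = compare_to_per_nut_length(result.transition, summary)
    if config.run_null:
        model = MarkovChain().fit(stream)
        result.null = null_max_distance(
            model, stream.N, observed=est.max_distance_,
            n_sims=config.null_n_sims, d_max=config.d_max,
            n_perm=config.n_perm, seed=seed,
        )
    return result


def run_individual(corpus: Corpus, config: RunConfig,
                   seed: Optional[int] = None) -> IndividualResult:
    """Full analysis bundle for one individual's corpus.

    Corpora shorter than ``config.min_corpus_length`` actions are excluded:
    entropy estimation from so few samples is dominated by bias.
    """
    summary = summarize_corpus(corpus)
    result = IndividualResult(individual_id=corpus.individual_id, summary=summary)
    stream = corpus.concatenated
    if stream.N < config.min_corpus_length:
        result.excluded = True
        result.exclusion_reason = (
            f"corpus of {stream.N} actions is below the {config.min_corpus_length}-action "
            "minimum for reliable entropy estimation"
        )
        logger.info("%s excluded: %s", corpus.individual_id, result.exclusion_reason)
        return result
    seed = config.seed if seed is None else seed
    result.variants["raw"] = _analyse_variant(stream, "raw", summary, config, seed)
    if config.condensed_variant:
        result.variants["condensed"] = _analyse_variant(
            condense(stream), "condensed", summary, config,
            None if seed is None else seed + 1,
        )
    return result


def mean_sd(values) -> tuple:
    """Cross-individual mean and sample (n-1) standard deviation."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("no values to aggregate")
    return float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else float("nan")


@dataclass
class StudyReport:
    """Study-level tables and aggregates across individuals."""

    individuals: dict
    summary_table: pd.DataFrame
    results_table: pd.DataFrame
    model_table: pd.DataFrame
    aggregates: dict
    community: object = None
    community_condensed: object = None


def run_study(corpora: dict, config: RunConfig) -> StudyReport:
    """Run every individual plus the community experiment and aggregate."""
    if not corpora:
        raise ValueError("empty study: no corpora supplied")
    individuals = {}
    base = config.seed
    for i, ind in enumerate(sorted(corpora)):
        seed = None if base is None else base + 1000 * i
        individuals[ind] = run_individual(corpora[ind], config, seed=seed)

    summary_rows, result_rows, model_rows = [], [], []
    for ind, res in individuals.items():
        s = res.summary
        summary_rows.append({
            "individual": ind, "n_sequences": s.n_sequences, "n_elements": s.n_elements,
            "n_action_types": s.n_action_types,
            "mean_seq_length": round(s.mean_seq_length, 1),
            "se_seq_length": round(s.se_seq_length, 1),
            "nuts_cracked": s.nuts_cracked,
            "mean_per_nut_length": None if s.mean_per_nut_length is None else round(s.mean_per_nut_length, 1),
            "se_per_nut_length": None if s.se_per_nut_length is None else round(s.se_per_nut_length, 1),
            "excluded": res.excluded,
        })
        for variant, vr in res.variants.items():
            result_rows.append({
                "individual": ind, "variant": variant,
                "max_distance": vr.max_distance, "censored": vr.censored,
                "preferred_model": vr.preferred_model,
                "best_set": ",".join(vr.comparison.best_set) if vr.comparison else "",
                "transition_point": vr.transition.transition_distance if vr.transition else None,
                "null_mean": vr.null.mean if vr.null else None,
                "null_ci_low": vr.null.ci_low if vr.null else None,
                "null_ci_high": vr.null.ci_high if vr.null else None,
                "null_verdict": vr.null.verdict if vr.null else None,
            })
            if vr.comparison is not None:
                tbl = vr.comparison.table.copy()
                tbl.insert(0, "variant", variant)
                tbl.insert(0, "individual", ind)
                tbl.insert(2, "max_distance", vr.max_distance)
                model_rows.append(tbl)

    results_table = pd.DataFrame(result_rows)
    aggregates = {}
    for variant in ("raw", "condensed"):
        sub = results_table[results_table["variant"] == variant]
        if sub.empty:
            continue
        m, sd = mean_sd(sub["max_distance"])
        aggregates[f"max_distance_mean_{variant}"] = m
        aggregates[f"max_distance_sd_{variant}"] = sd
        uncensored = sub[~sub["censored"]]
        if len(uncensored) and len(uncensored) < len(sub):
            m, sd = mean_sd(uncensored["max_distance"])
            aggregates[f"max_distance_mean_{variant}_uncensored"] = m
            aggregates[f"max_distance_sd_{variant}_uncensored"] = sd
        transitions = sub["transition_point"].dropna()
        if len(transitions):
            aggregates[f"transition_mean_{variant}"] = float(transitions.mean())

    report = StudyReport(
        individuals=individuals,
        summary_table=pd.DataFrame(summary_rows),
        results_table=results_table,
        model_table=pd.concat(model_rows, ignore_index=True) if model_rows else pd.DataFrame(),
        aggregates=aggregates,
    )

    if config.community_n_sequences > 0:
        included = [res for res in individuals.values() if not res.excluded]
        if included:
            pooled_syms = []
            for ind in sorted(corpora):
                if not individuals[ind].excluded:
                    pooled_syms.extend(corpora[ind].concatenated.symbols)
            from .corpus import TokenStream

            pooled = TokenStream(tuple(pooled_syms))
            report.community = community_experiment(
                pooled, n_sequences=config.community_n_sequences,
                sim_length=config.community_sim_length, d_max=config.d_max,
                n_perm=config.n_perm, tie_threshold=config.tie_threshold,
                seed=base,
            )
            if config.condensed_variant:
                report.community_condensed = community_experiment(
                    pooled, n_sequences=config.community_n_sequences,
                    sim_length=config.community_sim_length, d_max=config.d_max,
                    n_perm=config.n_perm, tie_threshold=config.tie_threshold,
                    condensed=True, seed=None if base is None else base + 1,
                )
    return report
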