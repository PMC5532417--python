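"""Core + sensitivity analysis matrix per outcome, from arm table to report.

Every outcome runs one core analysis (random effects, adjusted for mean
age and percent female, short-term trials excluded) plus a fixed set of
sensitivity variants: effect-model swaps, unadjusted models, for the
continuous outcome an additional baseline-severity covariate, and for
CGI-I response inclusion of the short-term trials.  A treatment-label
override per variant supports the methylphenidate ER-to-IR
reclassification sensitivity.

Per-variant seeds are derived by hashing the master seed with the variant
label, so adding or removing a variant never perturbs the others, and the
whole pipeline is byte-reproducible for a fixed master seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .diagnostics import (
    ConvergenceReport,
    DICReport,
    HeterogeneityResult,
    convergence_report,
    dic,
    pairwise_heterogeneity,
)
from .model import EffectModel, MCMCConfig, ModelSpec, PriorSpec, build_model, run_mcmc
from .summaries import SummaryTable, pooled_placebo_risk, summarize_outcome
from .trial_data import (
    Outcome,
    Treatment,
    TrialSet,
    ValidationError,
    apply_treatment_overrides,
    build_network,
    check_connectivity,
    filter_trials,
)

__all__ = [
    "AnalysisVariant",
    "AnalysisPlan",
    "VariantResult",
    "AnalysisReport",
    "default_plan",
    "run_plan",
    "export_report",
]

CORE_COVARIATES = ("mean_age", "pct_female")
DEFAULT_ANCHORS = (Treatment.GXR, Treatment.ATX)


@dataclass(frozen=True)
class AnalysisVariant:
    label: str
    effect_model: EffectModel
    covariates: tuple[str, ...]
    include_short_term: bool = False
    overrides: Mapping[str, str] = field(default_factory=dict)

    def spec(self, outcome: Outcome) -> ModelSpec:
        return ModelSpec(
            outcome=outcome,
            effect_model=self.effect_model,
            covariates=self.covariates,
            include_short_term=self.include_short_term,
        )


@dataclass
class AnalysisPlan:
    outcome: Outcome
    variants: tuple[AnalysisVariant, ...]
    mcmc: MCMCConfig = MCMCConfig()
    priors: PriorSpec = PriorSpec()
    anchors: tuple[Treatment, ...] = DEFAULT_ANCHORS
    reference_drug: Treatment = Treatment.GXR

    def __post_init__(self) -> None:
        cores = [v for v in self.variants if v.label == "core"]
        if len(cores) != 1:
            raise ValueError("plan must contain exactly one variant labeled 'core'")
        core = cores[0]
        if (
            core.effect_model is not EffectModel.RANDOM
            or core.covariates != CORE_COVARIATES
            or core.include_short_term
        ):
            raise ValueError(
                "core variant must be random effects, adjusted for mean_age and "
                "pct_female, excluding short-term trials"
            )


def default_plan(
    outcome: Outcome,
    mcmc: MCMCConfig | None = None,
    priors: PriorSpec | None = None,
    overrides: Mapping[str, str] | None = None,
) -> AnalysisPlan:
    """The published sensitivity matrix for one outcome.

    Continuous score change: core + 5 sensitivities (two of them adding
    the baseline severity covariate).  CGI-I response: core + 5 (two of
    them admitting short-term trials).  Discontinuation outcomes: core + 3.
    """
    ovr = dict(overrides or {})
    core = AnalysisVariant("core", EffectModel.RANDOM, CORE_COVARIATES, overrides=ovr)
    s_fixed_adj = AnalysisVariant("fixed_adjusted", EffectModel.FIXED, CORE_COVARIATES, overrides=ovr)
    s_rand_unadj = AnalysisVariant("random_unadjusted", EffectModel.RANDOM, (), overrides=ovr)
    s_fixed_unadj = AnalysisVariant("fixed_unadjusted", EffectModel.FIXED, (), overrides=ovr)
    variants = [core, s_fixed_adj, s_rand_unadj, s_fixed_unadj]
    if outcome is Outcome.ADHDRS_CHANGE:
        with_baseline = CORE_COVARIATES + ("baseline_adhdrs",)
        variants += [
            AnalysisVariant("random_baseline_adjusted", EffectModel.RANDOM, with_baseline, overrides=ovr),
            AnalysisVariant("fixed_baseline_adjusted", EffectModel.FIXED, with_baseline, overrides=ovr),
        ]
    elif outcome is Outcome.CGI_I:
        variants += [
            AnalysisVariant(
                "random_with_short_term", EffectModel.RANDOM, CORE_COVARIATES, True, overrides=ovr
            ),
            AnalysisVariant(
                "fixed_with_short_term", EffectModel.FIXED, CORE_COVARIATES, True, overrides=ovr
            ),
        ]
    return AnalysisPlan(
        outcome=outcome,
        variants=tuple(variants),
        mcmc=mcmc or MCMCConfig(),
        priors=priors or PriorSpec(),
    )


def variant_seed(master_seed: int, label: str) -> int:
    """Stable per-variant seed below 2^31, independent of variant order."""
    h = hashlib.sha256(f"{master_seed}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class VariantResult:
    label: str
    summary: SummaryTable | None
    dic_report: DICReport | None
    convergence: ConvergenceReport | None
    heterogeneity: tuple[HeterogeneityResult, ...]
    n_trials: int
    seed: int
    error: str | None = None


@dataclass
class AnalysisReport:
    outcome: Outcome
    variants: tuple[VariantResult, ...]
    master_seed: int
    mcmc: MCMCConfig
    input_digest: str
    version: str


def _heterogeneity_all_pairs(ts: TrialSet, outcome: Outcome) -> list[HeterogeneityResult]:
    treats = ts.treatments()
    out = []
    for i in range(len(treats)):
        for j in range(i + 1, len(treats)):
            try:
                out.append(pairwise_heterogeneity(ts, (treats[i], treats[j]), outcome))
            except ValueError:
                continue  # pair compared in fewer than two trials
    return out


def run_plan(ts: TrialSet, plan: AnalysisPlan, master_seed: int = 0) -> AnalysisReport:
    """Run every variant: filter, connectivity check, fit, summarize, diagnose.

    A failing sensitivity variant is recorded and the rest still run; a
    disconnected core network is a hard error.
    """
    from . import __version__

    digest = hashlib.sha256(ts.digest_text().encode()).hexdigest()
    results: list[VariantResult] = []
    for variant in plan.variants:
        seed = variant_seed(master_seed, variant.label)
        try:
            vts = apply_treatment_overrides(ts, variant.overrides) if variant.overrides else ts
            vts = filter_trials(
                vts,
                plan.outcome,
                exclude_short_term=not variant.include_short_term,
                required_covariates=variant.covariates,
            )
            net = build_network(vts, plan.outcome)
            report = check_connectivity(net, anchors=plan.anchors)
            if not report.connected:
                raise ValidationError(
                    f"network disconnected for variant {variant.label}: "
                    f"{len(report.components)} components, "
                    f"missing anchors {[t.value for t in report.missing_anchors]}"
                )
            ms = build_model(vts, variant.spec(plan.outcome))
            cfg = MCMCConfig(
                burn_in=plan.mcmc.burn_in,
                samples=plan.mcmc.samples,
                chains=plan.mcmc.chains,
                seed=seed,
                thin=plan.mcmc.thin,
            )
            draws = run_mcmc(ms, plan.priors, cfg)
            pooled = (
                pooled_placebo_risk(vts, plan.outcome) if plan.outcome.is_binary else None
            )
            summary = summarize_outcome(
                draws, pooled, reference_drug=plan.reference_drug, seed=seed
            )
            results.append(
                VariantResult(
                    label=variant.label,
                    summary=summary,
                    dic_report=dic(draws, ms),
                    convergence=convergence_report(draws),
                    heterogeneity=tuple(_heterogeneity_all_pairs(vts, plan.outcome)),
                    n_trials=len(vts.trials),
                    seed=seed,
                )
            )
        except Exception as exc:  # noqa: BLE001 - variant isolation by design
            if variant.label == "core":
                raise
            results.append(
                VariantResult(
                    label=variant.label,
                    summary=None,
                    dic_report=None,
                    convergence=None,
                    heterogeneity=(),
                    n_trials=0,
                    seed=seed,
                    error=str(exc),
                )
            )
    return AnalysisReport(
        outcome=plan.outcome,
        variants=tuple(results),
        master_seed=master_seed,
        mcmc=plan.mcmc,
        input_digest=digest,
        version=__version__,
    )


def _sha256_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def export_report(report: AnalysisReport, out_dir) -> dict[str, str]:
    """Write per-variant tables, diagnostics and densities plus a manifest.

    Returns the manifest mapping (relative file name -> sha256 digest);
    re-exporting an identical report yields identical digests.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    for vr in report.variants:
        base = f"{report.outcome.value.lower()}_{vr.label}"
        if vr.error is not None:
            p = out / f"{base}_error.json"
            p.write_text(json.dumps({"label": vr.label, "error": vr.error}, sort_keys=True))
            files.append(p)
            continue
        p = out / f"{base}_summary.csv"
        vr.summary.to_csv(p)
        files.append(p)
        diag = {
            "label": vr.label,
            "seed": vr.seed,
            "n_trials": vr.n_trials,
            "dic": vr.dic_report.to_dict(),
            "convergence": vr.convergence.to_dict(),
            "heterogeneity": [h.to_dict() for h in vr.heterogeneity],
        }
        p = out / f"{base}_diagnostics.json"
        p.write_text(json.dumps(diag, sort_keys=True, default=float))
        files.append(p)
        dens_rows = []
        for treat, dens in vr.summary.densities.items():
            d = dens.copy()
            d.insert(0, "treatment", treat)
            dens_rows.append(d)
        if dens_rows:
            import pandas as pd

            p = out / f"{base}_density.csv"
            pd.concat(dens_rows, ignore_index=True).to_csv(p, index=False)
            files.append(p)

    manifest = {
        "outcome": report.outcome.value,
        "master_seed": report.master_seed,
        "mcmc": {
            "burn_in": report.mcmc.burn_in,
            "samples": report.mcmc.samples,
            "chains": report.mcmc.chains,
            "thin": report.mcmc.thin,
        },
        "input_digest": report.input_digest,
        "version": report.version,
        "files": {f.name: _sha256_file(f) for f in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest["files"]
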