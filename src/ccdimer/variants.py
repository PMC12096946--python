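"""Per-variant structural impact reports.

Compares wild-type and mutant replicate ensembles in up to three
contexts -- the isolated protomer, the homodimer, and the heterodimer
with a partner coiled coil -- and emits wild-type-normalized metrics
(inter-/intra-protomer contacts, backbone hydrogen bonds, helicity,
contacts at the mutation site), pooled-variance one-tailed p-values and
a per-context impact call.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from . import chemistry as chem
from .contacts import (ContactStats, atom_contacts, backbone_hbond_count,
                       contact_stats, inter_chain_contacts, intra_chain_contacts)
from .secondary import ensemble_helicity
from .structure import Model, Selection, StructureEnsemble, select

CONTEXTS = ("protomer", "homodimer", "heterodimer")
# the metric that drives the impact call in each context
HEADLINE_METRIC = {"protomer": "backbone_hbonds",
                   "homodimer": "inter_protomer_contacts",
                   "heterodimer": "site_contacts"}


@dataclass(frozen=True)
class VariantSpec:
    label: str       # e.g. "L35P"
    chain: str
    position: int
    from_aa: str     # 1-letter
    to_aa: str       # 1-letter


def parse_variant(label: str, chain: str = "A") -> VariantSpec:
    """Parse a label like 'L35P' into a VariantSpec."""
    label = label.strip()
    if len(label) < 3 or not label[1:-1].isdigit():
        raise ValueError(f"cannot parse variant label {label!r}")
    return VariantSpec(label=label, chain=chain, position=int(label[1:-1]),
                       from_aa=label[0].upper(), to_aa=label[-1].upper())


def check_variant_matches(model: Model, variant: VariantSpec) -> None:
    res = model.residue(variant.chain, variant.position)
    if res is None:
        raise ValueError(f"position {variant.chain}{variant.position} absent")
    expected = chem.AA_1TO3[variant.from_aa]
    if res.name != expected:
        raise ValueError(f"wild-type structure has {res.name} at "
                         f"{variant.chain}{variant.position}, expected {expected}")


@dataclass
class ImpactThresholds:
    reduced_max: float = 0.8
    slight_min: float = 1.05
    enhanced_min: float = 1.2
    alpha: float = 0.05


def classify_impact(normalized: float, p: float,
                    thresholds: ImpactThresholds | None = None) -> str:
    """Map a wt-normalized metric + p-value to an impact call."""
    th = thresholds or ImpactThresholds()
    if normalized <= 0:
        raise ValueError("normalized metric must be positive")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if p < th.alpha:
        if normalized <= th.reduced_max:
            return "reduced"
        if normalized >= th.enhanced_min:
            return "enhanced"
        if normalized >= th.slight_min:
            return "slightly_enhanced"
    return "no_effect"


def site_contacts(model_or_ensemble, variant: VariantSpec, partner_chain: str,
                  cutoff: float = 10.0) -> tuple[list[int], float]:
    """Heavy-atom contacts between the variant residue and the partner chain.

    Returns (per-model counts, mean).  Accepts a single model or an
    ensemble.
    """
    if isinstance(model_or_ensemble, StructureEnsemble):
        models = model_or_ensemble.models
    else:
        models = [model_or_ensemble]
    counts = []
    for model in models:
        res = model.residue(variant.chain, variant.position)
        if res is None:
            raise ValueError(f"position {variant.chain}{variant.position} absent")
        ga = res.heavy_atoms()
        gb = select(model, Selection(chains=[partner_chain], heavy_only=True))
        counts.append(len(atom_contacts(model, ga, gb, cutoff)))
    return counts, float(np.mean(counts))


@dataclass
class VariantReport:
    variant: VariantSpec
    metrics: dict[str, dict[str, ContactStats]] = field(default_factory=dict)
    calls: dict[str, str] = field(default_factory=dict)
    thresholds: ImpactThresholds = field(default_factory=ImpactThresholds)
    schema_version: str = "1"

    def to_json(self) -> str:
        payload = {
            "schema_version": self.schema_version,
            "variant": asdict(self.variant),
            "thresholds": asdict(self.thresholds),
            "contexts": {
                ctx: {
                    "call": self.calls.get(ctx, "not_assessed"),
                    "metrics": {name: asdict(st) for name, st in stats.items()},
                } for ctx, stats in self.metrics.items()
            },
            "calls": self.calls,
        }
        return json.dumps(payload, indent=2, default=float)

    def table(self) -> pd.DataFrame:
        rows = []
        for ctx, stats in self.metrics.items():
            for name, st in stats.items():
                rows.append({
                    "context": ctx, "metric": name,
                    "wt_mean": st.wt_mean, "mut_mean": st.mut_mean,
                    "normalized": st.normalized, "p": st.p,
                    "headline": name == HEADLINE_METRIC.get(ctx),
                })
        return pd.DataFrame(rows)


def _context_metric_means(ensembles: Sequence[StructureEnsemble], context: str,
                          variant: VariantSpec, partner_chain: str
                          ) -> dict[str, list[float]]:
    """Per-replicate means (over frames) of each metric in one context."""
    out: dict[str, list[float]] = {}

    def push(name: str, value: float) -> None:
        out.setdefault(name, []).append(value)

    for ens in ensembles:
        chains = ens.first.chains
        chain = variant.chain if variant.chain in chains else chains[0]
        if context == "heterodimer":
            counts, mean = site_contacts(ens, variant, partner_chain)
            push("site_contacts", mean)
            continue
        hb = [backbone_hbond_count(m, Selection(chains=[chain]))
              for m in ens.models]
        push("backbone_hbonds", float(np.mean(hb)))
        hel_mean, _ = ensemble_helicity(ens, Selection(chains=[chain]))
        push("helicity", hel_mean)
        if context == "homodimer" and len(chains) >= 2:
            other = [c for c in chains if c != chain][0]
            inter = [len(inter_chain_contacts(m, chain, other))
                     for m in ens.models]
            intra = [len(intra_chain_contacts(m, chain)) for m in ens.models]
            push("inter_protomer_contacts", float(np.mean(inter)))
            push("intra_protomer_contacts", float(np.mean(intra)))
    return out


def build_report(wt_ensembles: dict[str, Sequence[StructureEnsemble]],
                 mut_ensembles: dict[str, Sequence[StructureEnsemble]],
                 variant: VariantSpec, partner_chain: str = "B",
                 thresholds: ImpactThresholds | None = None) -> VariantReport:
    """Full wt-vs-mutant comparison across the provided contexts.

    ``wt_ensembles``/``mut_ensembles`` map context name (protomer,
    homodimer, heterodimer) to a list of replicate ensembles (>= 2).
    Contexts present in only one of the two inputs are marked
    ``not_assessed``.
    """
    th = thresholds or ImpactThresholds()
    report = VariantReport(variant=variant, thresholds=th)
    for ctx in CONTEXTS:
        if ctx not in wt_ensembles or ctx not in mut_ensembles:
            if ctx in wt_ensembles or ctx in mut_ensembles:
                report.calls[ctx] = "not_assessed"
            continue
        wt_metrics = _context_metric_means(wt_ensembles[ctx], ctx, variant,
                                           partner_chain)
        mut_metrics = _context_metric_means(mut_ensembles[ctx], ctx, variant,
                                            partner_chain)
        stats = {name: contact_stats(wt_metrics[name], mut_metrics[name])
                 for name in wt_metrics if name in mut_metrics}
        report.metrics[ctx] = stats
        headline = stats.get(HEADLINE_METRIC[ctx])
        if headline is not None:
            report.calls[ctx] = classify_impact(headline.normalized, headline.p, th)
        else:
            report.calls[ctx] = "not_assessed"
    return report
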