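"""End-to-end two-condition analysis on simulated or loaded data.

Chains the library stages the way the comparative study runs them:
normalize per-chromosome matrices, call compartments in each condition,
detect switches, extract switched-compartment genes, integrate expression
and test pathway over-representation.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import compartments as comp
from . import contacts, enrichment, expression, simulate
from .genome import GenomeBins


@dataclass
class TwoConditionResult:
    truth: simulate.PlantedTruth
    profiles: dict[int, comp.CompartmentProfile]
    switches: comp.SwitchCall
    scgs: pd.DataFrame
    expression_summary: dict[int, dict]
    enrichment_table: pd.DataFrame


def normalize_all(
    matrices: dict[str, contacts.ContactMatrix],
) -> dict[str, contacts.ContactMatrix]:
    return {c: contacts.normalize_observed_expected(m) for c, m in matrices.items()}


def compartment_profile(
    raw_by_chrom: dict[str, contacts.ContactMatrix],
    bins: GenomeBins,
    genes: pd.DataFrame,
) -> comp.CompartmentProfile:
    """Raw matrices -> O/E -> correlation -> E1 -> oriented A/B labels."""
    density = expression.gene_density(genes, bins)
    return comp.call_profile(normalize_all(raw_by_chrom), bins, density)


def run_two_condition_analysis(
    config: simulate.SimConfig, seed: int | None = None
) -> TwoConditionResult:
    """Simulate both conditions and run the full comparative analysis.

    Contacts are simulated at the compartment resolution; compartments are
    called per condition, switches detected, switched-compartment genes
    extracted, per-condition expression summarized, and the switched genes
    tested against the simulated pathway collection (universe = all genes
    with a bin assignment).
    """
    if seed is not None:
        config = config.with_(seed=seed)
    truth = simulate.generate_truth(config)
    profiles = {}
    for cond in (1, 2):
        raw = simulate.simulate_hic(truth, config, cond, truth.comp_bins)
        profiles[cond] = compartment_profile(raw, truth.comp_bins, truth.genes)
    switches = comp.detect_switches(profiles[1], profiles[2])
    scgs = comp.extract_scgs(switches, truth.genes)

    expr_summary = {}
    lengths = truth.genes.set_index("gene_id")["length"]
    for cond in (1, 2):
        counts = simulate.simulate_expression(truth, config, cond)
        counts = counts.set_index("gene_id")["count"]
        fpkm = pd.Series(
            expression.compute_fpkm(
                counts.to_numpy(), lengths.loc[counts.index].to_numpy()
            ),
            index=counts.index,
        )
        expr_summary[cond] = expression.compartment_expression(
            profiles[cond], truth.genes, fpkm
        )

    pathways = simulate.simulate_pathways(truth, config)
    universe = set(truth.genes["gene_id"])
    if len(scgs):
        enr = enrichment.hypergeom_enrich(set(scgs["gene_id"]), pathways, universe)
    else:
        enr = pd.DataFrame()
    return TwoConditionResult(truth, profiles, switches, scgs, expr_summary, enr)
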