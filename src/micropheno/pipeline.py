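"""End-to-end deterministic analysis pipeline on synthetic data.

Runs the full chain — simulate a cohort, rarefy, close to relative
abundances, filter rare taxa, residualize the phenotype, two-part
association scan, cross-validated variance explained, co-abundance network
on the associated taxa, high/low group contrasts and SCFA statistics — and
writes every result as tab-delimited text plus a JSON summary. With the
same seed and parameters, outputs are byte-identical across runs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import canet, groupstats, mve, syndata, tables, twopart

__all__ = ["run_pipeline"]


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(n)]


def run_pipeline(
    outdir,
    seed: int = 0,
    n_samples: int = 105,
    n_taxa: int = 120,
    n_causal: int = 6,
    effect: float = 1.5,
    library_size_mean: int = 40_000,
    rarefaction_depth: int = 35_000,
    B: int = 1000,
    n_repeats_cv: int = 50,
    n_network_taxa: int = 15,
    n_per_group: int = 5,
) -> dict:
    """Run the whole analysis on a simulated cohort; returns a summary dict.

    ``n_network_taxa`` caps the co-abundance network at the top taxa by
    association (the network stage targets phenotype-associated taxa).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    s_sim, s_rarefy, s_scan, s_cv, s_net = _spawn_seeds(seed, 5)

    # two causal blocks with opposite effect signs and within-block basis
    # correlation, mirroring positively / negatively associated co-abundance
    # groups. Causal taxa are picked from a pre-pass of the count generator
    # so they are prevalent and abundant enough to survive the rare-taxon
    # filter (an effect planted on a filtered-out taxon is unobservable by
    # construction).
    base = dict(
        n_samples=n_samples,
        n_taxa=n_taxa,
        library_size_mean=library_size_mean,
        prevalence_range=(0.4, 1.0),
        noise_sd=1.0,
        sex_effect=0.5,
        cage_effect_sd=0.3,
        intercept=2500.0,
        seed=s_sim,
    )
    pre = syndata.gen_count_table(syndata.SimulationConfig(**base))
    prev = (pre.counts > 0).mean(axis=0)
    mean_ab = (pre.counts / pre.counts.sum(axis=1, keepdims=True)).mean(axis=0)
    # near-ubiquitous abundant taxa: abundance-shift effects whose pairwise
    # basis correlations survive closure and zero-handling, so the planted
    # co-abundance blocks are observable downstream
    eligible = np.flatnonzero((prev >= 0.95) & (mean_ab >= 0.003))
    eligible = eligible[np.argsort(-mean_ab[eligible])]
    causal = sorted(int(j) for j in eligible[:n_causal])
    n_pos = (len(causal) + 1) // 2
    signs = np.array([1.0] * n_pos + [-1.0] * (len(causal) - n_pos))
    pairs = [
        (a, b, 0.8)
        for grp in (causal[:n_pos], causal[n_pos:])
        for i, a in enumerate(grp)
        for b in grp[i + 1 :]
    ]
    cfg = syndata.SimulationConfig(
        **base,
        n_causal_taxa=len(causal),
        causal_taxa=causal,
        beta1_effects=effect * signs,
        beta2_effects=effect * signs,
        basis_correlation_pairs=pairs,
    )
    counts = syndata.gen_count_table(cfg)
    pheno, truth = syndata.gen_phenotype(counts, cfg)
    scfa = syndata.gen_scfa(counts, truth.causal_taxa[: max(n_causal // 2, 1)], effect=0.5, seed=s_sim)

    tables.write_count_table(counts, out / "counts.tsv")
    syndata.write_truth(truth, out / "truth.json")
    scfa.to_frame().to_csv(out / "scfa.tsv", sep="\t", index_label="sample_id")

    rare = tables.rarefy(counts, rarefaction_depth, seed=s_rarefy)
    abund = tables.to_relative(rare)
    abund, report = tables.filter_taxa(abund)
    with open(out / "filter_report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)

    keep = [s in set(rare.sample_ids) for s in pheno.sample_ids]
    idx = np.flatnonzero(keep)
    pheno = tables.PhenotypeFrame(
        [pheno.sample_ids[i] for i in idx],
        pheno.phenotype[idx], pheno.sex[idx], pheno.cage[idx],
    )
    pheno = tables.residualize(pheno)
    tables.write_phenotype(pheno, out / "phenotype.tsv")

    assoc = twopart.two_part_scan(abund, pheno, B=B, seed=s_scan)
    assoc.to_csv(out / "twopart.tsv", sep="\t", index=False, float_format="%.10g")

    ve = mve.cross_validate(abund, pheno, n_repeats=n_repeats_cv, B_inner=0, seed=s_cv)
    ve.to_frame().to_csv(out / "variance_explained.tsv", sep="\t", index=False, float_format="%.10g")

    # network over the most-associated taxa present in the filtered table
    order = assoc.sort_values(["p_final", "taxon_id"]).taxon_id.tolist()
    net_taxa = order[: min(n_network_taxa, len(order))]
    cols = [abund.taxon_ids.index(t) for t in net_taxa]
    net_counts = rare.counts[:, [rare.taxon_ids.index(t) for t in net_taxa]]
    network = canet.build_canet(
        net_counts, taxon_ids=net_taxa, seed=s_net, n_perm_edges=4999, n_outer=10
    )
    network.edges.to_csv(out / "network_edges.tsv", sep="\t", index=False, float_format="%.10g")
    cag_df = canet.cag_phenotype_corr(
        network.cag_labels,
        tables.AbundanceTable(abund.sample_ids, net_taxa, _renorm(abund.fractions[:, cols])),
        pheno,
    )
    cag_df.to_csv(out / "cag_phenotype.tsv", sep="\t", index=False, float_format="%.10g")

    design = groupstats.select_extremes(pheno, n_per_group=n_per_group)
    wil = groupstats.wilcoxon_fdr(abund, design)
    wil.to_csv(out / "wilcoxon.tsv", sep="\t", index=False, float_format="%.10g")
    scfa_kept = _subset_scfa(scfa, pheno.sample_ids)
    tt = groupstats.ttest_fdr(scfa_kept, design)
    tt.to_csv(out / "scfa_ttest.tsv", sep="\t", index=False, float_format="%.10g")
    sp = groupstats.spearman_fdr(abund, scfa_kept)
    sp.to_csv(out / "scfa_spearman.tsv", sep="\t", index=False, float_format="%.10g")

    n_sig = int((assoc["q_value"] < 0.05).sum())
    summary = {
        "seed": seed,
        "n_samples": int(abund.n_samples),
        "n_taxa_after_filter": int(abund.n_taxa),
        "n_associated_q05": n_sig,
        "n_network_edges": int(len(network.edges)),
        "permanova_p": float(network.permanova_p),
        "mean_R2_most_permissive": float(ve.mean_r2[-1]),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _renorm(frac: np.ndarray) -> np.ndarray:
    return frac / frac.sum(axis=1, keepdims=True)


def _subset_scfa(scfa, sample_ids):
    pos = {s: i for i, s in enumerate(scfa.sample_ids)}
    idx = [pos[s] for s in sample_ids]
    return groupstats.ScfaTable(
        list(sample_ids), scfa.acetate[idx], scfa.propionate[idx], scfa.butyrate[idx]
    )
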