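"""Pipeline orchestrator: run the analysis stages from one config file.

The config is TOML (a flat key = value file with optional [sections]).
Minimal example::

    seed = 1
    stages = ["trees", "coevolve", "selection", "codonusage", "geneconv"]

    [inputs]
    alignment = "family.fasta"
    domain_table = "domains.tsv"
    tree = "family.nwk"          # optional; NJ is built when absent

Each stage writes TSV tables into the output directory, plus a
``metadata.json`` with the seed, package version and parameters, so a
run is reproducible bit-for-bit from its report directory.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alignment import (
    CodonAlignment,
    read_alignment,
    read_protein_fasta,
    slice_domain,
    translate_alignment,
    write_alignment,
    write_domain_table,
)
from .codon_models import branch_site_scan, fit_m0, fit_model, lrt
from .codon_usage import codon_usage_stats, compare_groups, enc_gc3_table, usage_table
from .coevolution import coevolution_scan
from .errors import ConfigurationError, FamevolError
from .genome_scan import flank_duplication_scan, geneconv_scan
from .phenotype import anova_bonferroni, read_phenotype_table, tolerance_table
from .phylo import bootstrap_support, protein_distance_matrix
from .simulate import SimulationConfig, al_family_preset, simulate_alignment
from .trees import PhyloTree

ALL_STAGES = (
    "simulate", "trees", "coevolve", "selection",
    "codonusage", "dupscan", "geneconv", "phenotype",
)

_SITE_MODEL_PAIRS = (("M0", "M3", 4), ("M1a", "M2a", 2), ("M7", "M8", 2))


def load_config(path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def _fmt(x, nd=4):
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "NA"
    return f"{x:.{nd}f}" if isinstance(x, float) else str(x)


def run_pipeline(config, out: str | Path | None = None) -> dict:
    """Run the configured stages; returns a dict of stage results.

    ``config`` is a path to a TOML file or an already-parsed dict.
    """
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    outdir = Path(out if out is not None else cfg.get("out", "famevol_report"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    stages = list(cfg.get("stages", []))
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ConfigurationError(f"unknown stages {sorted(unknown)}")
    if not stages:
        raise ConfigurationError("config lists no stages")
    inputs = dict(cfg.get("inputs", {}))
    results: dict = {}

    aln: CodonAlignment | None = None
    tree: PhyloTree | None = None

    def require(stage, condition, what):
        if not condition:
            raise ConfigurationError(f"stage {stage!r} requires {what}")

    try:
        if "simulate" in stages:
            sim_cfg = dict(cfg.get("simulate", {}))
            preset = sim_cfg.pop("preset", None)
            sim_cfg.setdefault("seed", seed)
            sc = al_family_preset(**sim_cfg) if preset == "al-family" else SimulationConfig(**sim_cfg)
            aln, truth = simulate_alignment(sc)
            tree = truth.gene_family_tree
            write_alignment(aln, outdir / "simulated_cds.fasta")
            write_domain_table(aln.domains, outdir / "simulated_domains.tsv")
            (outdir / "true_tree.nwk").write_text(tree.to_newick() + "\n")
            (outdir / "truth.json").write_text(json.dumps({
                "kappa": truth.kappa,
                "rho": truth.rho,
                "sigma_b": truth.sigma_b,
                "omega_model": truth.omega_spec.model,
                "site_class": {k: v.tolist() for k, v in truth.site_class.items()},
                "branch_rates": truth.branch_rates,
            }, indent=1))
            results["simulate"] = {"alignment": aln, "truth": truth}

        if aln is None and "alignment" in inputs:
            aln = read_alignment(inputs["alignment"], inputs.get("domain_table"))
        if tree is None and "tree" in inputs:
            tree = PhyloTree.from_newick(Path(inputs["tree"]).read_text())

        needs_aln = [s for s in stages if s in
                     ("trees", "coevolve", "selection", "codonusage", "geneconv")]
        if needs_aln:
            require(needs_aln[0], aln is not None, "an alignment (input or simulate stage)")

        if "trees" in stages:
            tree_cfg = dict(cfg.get("trees", {}))
            B = int(tree_cfg.get("bootstrap", 1000))
            model = tree_cfg.get("distance_model", "poisson")
            domain_names = [d.name for d in aln.domains] or [None]
            stage_out = {}
            for name in domain_names:
                sub = slice_domain(aln, name) if name else aln
                prot = translate_alignment(sub)
                D = protein_distance_matrix(prot, model=model)
                tag = (name or "full").replace("/", "_")
                D.to_tsv(outdir / f"distances_{tag}.tsv")
                bt = bootstrap_support(prot, B=B, model=model, seed=seed)
                (outdir / f"nj_{tag}.nwk").write_text(bt.to_newick() + "\n")
                stage_out[name or "full"] = {"distances": D, "tree": bt}
            results["trees"] = stage_out

        if "coevolve" in stages:
            require("coevolve", len(aln.domains) >= 2, ">= 2 annotated domains")
            co_cfg = dict(cfg.get("coevolve", {}))
            res = coevolution_scan(
                aln,
                model=co_cfg.get("distance_model", "poisson"),
                n_perm=int(co_cfg.get("n_perm", 5000)),
                seed=seed,
            )
            df = pd.DataFrame([{
                "domain_a": r.domain_a, "domain_b": r.domain_b,
                "r_linear": r.r_linear, "r_mantel": r.r_mantel,
                "p_mantel": r.p_mantel, "n_perm": r.n_perm, "seed": seed,
            } for r in res])
            df.to_csv(outdir / "coevolution.tsv", sep="\t", index=False,
                      float_format="%.4f")
            results["coevolve"] = res

        if "selection" in stages:
            require("selection", tree is not None, "a tree (input or simulate stage)")
            sel_cfg = dict(cfg.get("selection", {}))
            models = sel_cfg.get("site_models", ["M0", "M1a", "M2a", "M3", "M7", "M8"])
            m0 = fit_m0(aln, tree)
            fits = {"M0": m0}
            for m in models:
                if m != "M0":
                    fits[m] = fit_model(aln, tree, m, m0_fit=m0)
            rows = []
            for m in models:
                f = fits[m]
                stat = p = None
                for null, altm, df_ in _SITE_MODEL_PAIRS:
                    if altm == m and null in fits:
                        t = lrt(f.lnL, fits[null].lnL, df_)
                        stat, p = t.stat, t.p
                pstr = ", ".join(f"{k}={_fmt(v)}" for k, v in sorted(f.params.items()))
                sites = "; ".join(f"{s}({q:.3f})" for s, q in f.positively_selected_sites)
                rows.append({
                    "model": m, "lnL": _fmt(f.lnL, 3), "parameters": pstr,
                    "LRT_2dl": _fmt(stat), "LRT_p": _fmt(p),
                    "positively_selected_sites": sites or
                        ("Not allowed" if not f.positive_classes else "None"),
                })
            pd.DataFrame(rows).to_csv(outdir / "site_models.tsv", sep="\t", index=False)
            results["selection"] = {"site": fits}

            clades = sel_cfg.get("clades", sorted(tree.clade_labels))
            if clades:
                scan = branch_site_scan(aln, tree, clades, m0_fit=m0)
                srows = []
                for r in scan:
                    a = r["alt"].params
                    pstr = ", ".join(
                        f"{k}={_fmt(a[k])}" for k in
                        ("p0", "p1", "p2a", "p2b", "omega0", "omega2") if k in a
                    )
                    sites = "; ".join(f"{s}({q:.3f})" for s, q in r["selected_sites"])
                    srows.append({
                        "clade": r["clade"], "lnL": _fmt(r["lnL_alt"], 3),
                        "parameters": pstr, "stat_2dl": _fmt(r["stat"]),
                        "p": _fmt(r["p"]),
                        "positively_selected_sites": sites or "Not found",
                    })
                pd.DataFrame(srows).to_csv(
                    outdir / "branch_site.tsv", sep="\t", index=False)
                results["selection"]["branch_site"] = scan

        if "codonusage" in stages:
            cu_cfg = dict(cfg.get("codonusage", {}))
            genes = {r.id: r.ungapped() for r in aln.rows}
            ref = list(genes.values())
            from .codon_usage import reference_weights
            weights = reference_weights(ref)
            stats_all = [codon_usage_stats(g, s, weights) for g, s in genes.items()]
            usage_table(stats_all).to_csv(
                outdir / "codon_usage.tsv", sep="\t", index=False, float_format="%.4f")
            enc_gc3_table(stats_all).to_csv(
                outdir / "enc_gc3.tsv", sep="\t", index=False, float_format="%.4f")
            # per-species group comparisons per region, Table-4 layout
            species = sorted({r.species for r in aln.rows if r.species})
            regions = {"gene": aln} | {
                d.name: slice_domain(aln, d.name) for d in aln.domains
            }
            comp_rows = []
            for i, sa in enumerate(species):
                for sb in species[i + 1:]:
                    row = {"comparison": f"{sa} vs {sb}"}
                    for reg_name, reg_aln in regions.items():
                        sub = {
                            r.id: r.ungapped() for r in reg_aln.rows
                        }
                        st = {g: codon_usage_stats(g, s, weights)
                              for g, s in sub.items()}
                        ga = [st[g] for g in st if g.startswith(sa)]
                        gb = [st[g] for g in st if g.startswith(sb)]
                        for metric in ("GC3", "ENC", "CAI"):
                            if metric == "CAI" and reg_name != "gene":
                                continue
                            try:
                                p = compare_groups(ga, gb, metric)
                            except FamevolError:
                                p = None
                            row[f"{reg_name}_{metric}"] = _fmt(p)
                    comp_rows.append(row)
            if comp_rows:
                pd.DataFrame(comp_rows).to_csv(
                    outdir / "codon_usage_comparisons.tsv", sep="\t", index=False)
            results["codonusage"] = stats_all

        if "dupscan" in stages:
            require("dupscan", "flanks_a" in inputs and "flanks_b" in inputs,
                    "flanks_a and flanks_b protein FASTAs")
            dcfg = dict(cfg.get("dupscan", {}))
            res = flank_duplication_scan(
                read_protein_fasta(inputs["flanks_a"]),
                read_protein_fasta(inputs["flanks_b"]),
                min_pairs=int(dcfg.get("min_pairs", 3)),
                identity_min=float(dcfg.get("identity_min", 70.0)),
                similarity_min=float(dcfg.get("similarity_min", 85.0)),
            )
            res["pairs"].to_csv(outdir / "duplication_pairs.tsv", sep="\t",
                                index=False, float_format="%.4f")
            (outdir / "duplication_call.txt").write_text(
                f"conserved_pairs\t{res['n_conserved']}\n"
                f"duplication_called\t{res['duplication_called']}\n")
            results["dupscan"] = res

        if "geneconv" in stages:
            gcfg = dict(cfg.get("geneconv", {}))
            calls = geneconv_scan(
                aln, n_perm=int(gcfg.get("n_perm", 10000)), seed=seed,
                alpha=float(gcfg.get("alpha", 0.05)),
            )
            pd.DataFrame([{
                "seq_a": c.id_a, "seq_b": c.id_b,
                "fragment_score": c.fragment_score,
                "tract_start": c.tract_start, "tract_end": c.tract_end,
                "p_sim": _fmt(c.p_sim), "p_corrected": _fmt(c.p_corrected),
            } for c in calls]).to_csv(
                outdir / "gene_conversion.tsv", sep="\t", index=False)
            results["geneconv"] = calls

        if "phenotype" in stages:
            require("phenotype", "phenotype" in inputs, "a phenotype TSV")
            pcfg = dict(cfg.get("phenotype", {}))
            df = read_phenotype_table(inputs["phenotype"])
            ti = tolerance_table(df, control_mM=float(pcfg.get("control_mM", 0.0)))
            ti.to_csv(outdir / "tolerance_index.tsv", sep="\t", index=False,
                      float_format="%.4f")
            anova_rows = []
            pair_frames = []
            for treatment, sub in ti.groupby("treatment_mM"):
                groups = {g: v.TI.tolist() for g, v in sub.groupby("genotype")}
                if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
                    continue
                res = anova_bonferroni(groups, alpha=float(pcfg.get("alpha", 0.01)))
                anova_rows.append({
                    "treatment_mM": treatment, "F": _fmt(res.F), "p": _fmt(res.p),
                    "df_between": res.df_between, "df_within": res.df_within,
                    "letters": "; ".join(f"{g}:{l}" for g, l in sorted(res.letters.items())),
                })
                pw = res.pairwise.copy()
                pw.insert(0, "treatment_mM", treatment)
                pair_frames.append(pw)
            pd.DataFrame(anova_rows).to_csv(outdir / "phenotype_anova.tsv",
                                            sep="\t", index=False)
            if pair_frames:
                pd.concat(pair_frames).to_csv(
                    outdir / "phenotype_pairwise.tsv", sep="\t", index=False,
                    float_format="%.4f")
            results["phenotype"] = anova_rows

    except ConfigurationError:
        raise
    except FamevolError as exc:
        stage = next((s for s in stages if s not in results), "?")
        raise type(exc)(f"stage {stage!r}: {exc}") from exc

    (outdir / "metadata.json").write_text(json.dumps({
        "package": "famevol",
        "version": __version__,
        "seed": seed,
        "stages": stages,
        "config": {k: v for k, v in cfg.items() if k != "inputs"} |
                  {"inputs": {k: str(v) for k, v in inputs.items()}},
    }, indent=1, default=str))
    return results
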