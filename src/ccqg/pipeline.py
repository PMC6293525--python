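"""End-to-end orchestration: simulate -> reconstruct -> process ->
heritability -> scan -> annotate, from a single config, with a
reproducibility manifest.

Every stage writes plain files so any stage can be re-run standalone;
identical config + seeds give byte-identical outputs and manifest
checksums.  Stage order mirrors the analysis chain: genome reconstruction,
covariate correction and quantile normalization, heritability (raw and
processed), weighted haplotype scan with permutation thresholds, then
gene annotation of significant QTLs.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import io
from .errors import InvalidArgumentError, StageError
from .herit import anova_broad_h2, fit_variance_components, kinship_from_descent
from .hmm import HmmParams, founder_contributions, prune_intervals, reconstruct_descent
from .pheno import TraitVector, adjust_covariates, line_summaries, quantile_normalize
from .scan import permutation_threshold, scan_genome, significant_qtls
from .simulate import (
    QtlEffect,
    QtlSpec,
    breed_cc_panel,
    genotype_panel,
    simulate_founders,
    simulate_gene_ranking,
    simulate_gene_table,
    simulate_phenotypes,
)

log = logging.getLogger("ccqg")

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "outdir": "ccqg_run",
    "simulate": {
        "n_lines": 20,
        "chr_lengths_cM": [70.0, 70.0],
        "markers_per_chrom": 250,
        "allele_freq": 0.5,
        "inbreeding_gens": 20,
        "funnels": "balanced",
        "genotype_error_rate": 0.005,
        "genotype_missing_rate": 0.02,
        "n_per_line": [5, 6],
        "sigma_g2": 0.0,
        "sigma_e2": 1.0,
        "age_effect": 0.0,
        "qtls": [],  # each: {chrom, pos_cm, effects: [8 floats]}
    },
    "trait": "trait",
    "hmm": {"error_rate": 0.01, "expansion": 2.0, "prune_to": None},
    "preprocessing": {
        "covariates": ["age", "batch", "origin"],
        "quantile_normalize": True,
    },
    "scan": {"n_perm": 200, "alphas": [0.05, 0.1, 0.5], "alpha": 0.05},
    "annotate": {"enabled": False, "n_genes": 500, "n_resample": 2000},
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


class PipelineConfig:
    """Validated pipeline configuration (defaults merged with overrides)."""

    def __init__(self, overrides: dict | None = None):
        self.data = _merge(DEFAULT_CONFIG, overrides or {})
        sim = self.data["simulate"]
        if sim["n_lines"] < 2:
            raise InvalidArgumentError("need at least 2 lines")
        for q in sim["qtls"]:
            if len(q.get("effects", [])) != 8:
                raise InvalidArgumentError("QTL effects must have length 8")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(io.load_config(path))

    def __getitem__(self, key):
        return self.data[key]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig | dict, outdir=None) -> dict:
    """Execute all stages and return (and write) the run manifest."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig(config)
    out = Path(outdir or config["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    ss = np.random.SeedSequence(seed)
    stage_seeds = {
        name: int(s.generate_state(1)[0] % 2**31)
        for name, s in zip(
            ["founders", "breeding", "genotyping", "phenotypes", "scan", "genes"],
            ss.spawn(6),
        )
    }
    manifest = {
        "package": "ccqg",
        "config": config.data,
        "seed": seed,
        "stage_seeds": stage_seeds,
        "files": {},
    }

    def emit(name: str, writer, *args):
        path = out / name
        writer(*args, path)
        manifest["files"][name] = _sha256(path)

    # -- stage 1: simulate -------------------------------------------------
    try:
        sim = config["simulate"]
        log.info("simulate: %d lines", sim["n_lines"])
        founders = simulate_founders(
            sim["markers_per_chrom"],
            sim["chr_lengths_cM"],
            allele_freq=sim["allele_freq"],
            seed=stage_seeds["founders"],
        )
        mosaics = breed_cc_panel(
            founders,
            sim["n_lines"],
            n_inbreeding_gens=sim["inbreeding_gens"],
            seed=stage_seeds["breeding"],
            funnels=sim.get("funnels"),
        )
        genotypes = genotype_panel(
            mosaics,
            founders,
            error_rate=sim["genotype_error_rate"],
            missing_rate=sim["genotype_missing_rate"],
            seed=stage_seeds["genotyping"],
        )
        qtl_spec = QtlSpec(
            qtls=tuple(
                QtlEffect(str(q["chrom"]), float(q["pos_cm"]), tuple(q["effects"]))
                for q in sim["qtls"]
            ),
            sigma_g2=float(sim["sigma_g2"]),
            sigma_e2=float(sim["sigma_e2"]),
            age_effect=float(sim.get("age_effect", 0.0)),
            batch_effects=sim.get("batch_effects", {}),
            origin_effects=sim.get("origin_effects", {}),
        )
        from .hmm import descent_from_truth

        true_probs = descent_from_truth(mosaics, founders.gmap)
        true_k = kinship_from_descent(true_probs)
        n_per_line = sim["n_per_line"]
        if isinstance(n_per_line, list):
            n_per_line = tuple(n_per_line)
        pheno = simulate_phenotypes(
            mosaics,
            true_k,
            qtl_spec,
            n_per_line=n_per_line,
            seed=stage_seeds["phenotypes"],
            trait=config["trait"],
        )
        emit("founders.csv", io.write_founders, founders)
        emit("genotypes.csv", io.write_genotypes, genotypes)
        emit("mosaics.tsv", io.write_mosaics, mosaics)
        emit("phenotypes.csv", io.write_phenotypes, pheno)
    except Exception as exc:  # noqa: BLE001
        raise StageError("simulate", str(exc)) from exc

    # -- stage 2: genome reconstruction -----------------------------------
    try:
        hmm_cfg = config["hmm"]
        params = HmmParams(
            error_rate=hmm_cfg["error_rate"], expansion=hmm_cfg["expansion"]
        )
        probs = reconstruct_descent(genotypes, founders, params)
        if hmm_cfg.get("prune_to"):
            probs = prune_intervals(probs, int(hmm_cfg["prune_to"]))
        contrib = founder_contributions(probs)
        emit("descent.csv", io.write_descent_wide, probs)
        (out / "founder_shares.json").write_text(
            json.dumps(
                {k: round(float(v), 6) for k, v in contrib.overall.items()},
                indent=1,
            )
        )
        manifest["files"]["founder_shares.json"] = _sha256(
            out / "founder_shares.json"
        )
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("reconstruct", str(exc)) from exc

    # -- stage 3: phenotype processing -------------------------------------
    try:
        trait_name = config["trait"]
        raw = TraitVector.from_frame(pheno, trait_name)
        covs = pheno[config["preprocessing"]["covariates"]]
        corrected = adjust_covariates(raw, covs)
        processed = (
            quantile_normalize(corrected)
            if config["preprocessing"]["quantile_normalize"]
            else corrected
        )
        lines = pheno["line"].to_numpy()
        summaries = line_summaries(processed, lines)
        emit(
            "line_summaries.tsv",
            lambda df, p: df.to_csv(p, sep="\t", index=False, float_format="%.6g"),
            summaries,
        )
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("pheno", str(exc)) from exc

    # -- stage 4: heritability ---------------------------------------------
    try:
        kin = kinship_from_descent(probs)
        emit("kinship.csv", io.write_kinship, kin)
        herit = {}
        for label, tv in (("raw", raw), ("processed", processed)):
            vc = fit_variance_components(tv, lines, kin)
            an = anova_broad_h2(tv, lines)
            herit[label] = {
                "h2": vc.h2,
                "sigma_g2": vc.sigma_g2,
                "sigma_e2": vc.sigma_e2,
                "loglik": vc.loglik,
                "boundary": vc.boundary,
                "H2": an.H2,
                "MS_between": an.ms_between,
                "MS_within": an.ms_within,
                "n_bar": an.n_bar,
                "anova_F": an.F,
                "anova_P": an.p_value,
                "Vg_clamped": an.clamped,
            }
        (out / "heritability.json").write_text(json.dumps(herit, indent=1))
        manifest["files"]["heritability.json"] = _sha256(out / "heritability.json")
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("herit", str(exc)) from exc

    # -- stage 5: QTL scan --------------------------------------------------
    try:
        scfg = config["scan"]
        means = summaries.set_index("line")["mean"]
        weights = summaries.set_index("line")["n"].astype(float)
        scan = scan_genome(means, weights, probs, trait=trait_name)
        perm = permutation_threshold(
            means,
            weights,
            probs,
            n_perm=int(scfg["n_perm"]),
            alphas=tuple(scfg["alphas"]),
            seed=stage_seeds["scan"],
            engine=scan.engine,
        )
        qtls = significant_qtls(scan, perm, alpha=float(scfg["alpha"]))
        emit("scan.tsv", io.write_scan, scan)
        emit("perm_maxima.tsv", io.write_permutations, perm)
        emit("qtls.tsv", io.write_qtls, qtls)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("scan", str(exc)) from exc

    # -- stage 6: annotation (optional) -------------------------------------
    try:
        acfg = config["annotate"]
        if acfg.get("enabled"):
            from .annotate import genes_in_interval, rank_enrichment

            if acfg.get("gene_table"):
                genes = io.read_gene_table(acfg["gene_table"])
                ranking = io.read_ranking(acfg["ranking"])
            else:
                genes = simulate_gene_table(
                    founders.gmap, acfg["n_genes"], seed=stage_seeds["genes"]
                )
                ranking = simulate_gene_ranking(
                    genes["gene_id"], seed=stage_seeds["genes"]
                )
            rows = []
            for i, q in enumerate(qtls):
                members = genes_in_interval(q, genes)
                if members.empty:
                    continue
                enr = rank_enrichment(
                    members["gene_id"],
                    ranking,
                    n_resample=acfg["n_resample"],
                    seed=stage_seeds["genes"] + i,
                    qtl_id=f"{q.trait}:{q.chrom}",
                )
                rows.append(
                    (enr.qtl_id, len(enr.genes), enr.statistic, enr.p_value,
                     enr.method)
                )
            import pandas as pd

            pd.DataFrame(
                rows, columns=["qtl", "n_genes", "statistic", "p", "method"]
            ).to_csv(out / "enrichment.tsv", sep="\t", index=False)
            manifest["files"]["enrichment.tsv"] = _sha256(out / "enrichment.tsv")
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("annotate", str(exc)) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    log.info("pipeline complete: %s", out)
    return manifest
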