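"""End-to-end orchestration: simulate -> profile -> analyze.

Each stage reads and writes the plain-text formats the ingest module
defines (multi-FASTA, taxonomy TSV, profile TSV) so stages can be re-run
independently; a JSON run manifest records the configuration, input hashes,
row counts and software version for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .composition import AMINO_ACIDS, BASES, CODONS, BiasMetrics, CompositionProfile, profile_genome
from .errors import ContractViolation, DegenerateModelError, EmptyInputError
from .multivariate import (
    cluster_genomes,
    export_heatmap_inputs,
    pca_correlation,
    regress_component_on_covariate,
    to_newick,
)
from .regression import (
    ModelSpec,
    RandomStructure,
    compare_aic,
    fit_anova_aaub_phylum,
    fit_at_on_codons,
    fit_gam,
    fit_gamm,
    fit_kl_vs_size,
)
from .seqio import read_cds_fasta, read_taxonomy_table, write_results_tsv
from .synthetic import CohortConfig, SimulatedCohort, simulate_cohort, write_cohort

logger = logging.getLogger(__name__)

NUC_COLUMNS = [f"nuc_{b}" for b in BASES]
CODON_COLUMNS = [f"codon_{c}" for c in CODONS]
AA_COLUMNS = [f"aa_{a}" for a in AMINO_ACIDS]
#: fixed, documented profile column order
PROFILE_COLUMNS = (
    ["at_fraction", "n_codons", "n_residues", "genome_size", "aaub", "cub", "kl"]
    + NUC_COLUMNS + CODON_COLUMNS + AA_COLUMNS
)


@dataclass
class AnalysisConfig:
    """Tunables for the analysis stage (spline basis, estimation criterion,
    hierarchy columns, phylum size threshold for AAUB rankings)."""

    basis_dim: int = 10
    method: str = "REML"
    hierarchy: tuple[str, ...] = ("phylum", "genus", "species")
    slope_on: str = "at_fraction"
    phylum_min_size: int = 20


def profiles_to_frame(
    profiles: list[CompositionProfile], metrics: list[BiasMetrics]
) -> pd.DataFrame:
    rows = {}
    for p, m in zip(profiles, metrics):
        rows[p.genome_id] = (
            [p.at_fraction, p.n_codons, p.n_residues, p.genome_size, m.aaub, m.cub, m.kl]
            + list(p.nuc_freq) + list(p.codon_freq) + list(p.aa_freq)
        )
    df = pd.DataFrame.from_dict(rows, orient="index", columns=PROFILE_COLUMNS)
    df.index.name = "genome_id"
    return df


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    stage: str
    version: str = __version__
    seed: int | None = None
    config: dict = field(default_factory=dict)
    input_hashes: dict = field(default_factory=dict)
    output_hashes: dict = field(default_factory=dict)
    row_counts: dict = field(default_factory=dict)
    timestamp: str = ""

    def write(self, path: str | Path) -> None:
        self.timestamp = self.timestamp or time.strftime("%Y-%m-%dT%H:%M:%S")
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)
            fh.write("\n")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def cmd_simulate(config: CohortConfig, out_dir: str | Path, seed: int | None = None) -> SimulatedCohort:
    """Simulate a cohort and write FASTA + taxonomy + truth tables."""
    cohort = simulate_cohort(config, seed=seed, sequences=True)
    out_dir = Path(out_dir)
    paths = write_cohort(cohort, out_dir)
    manifest = RunManifest(
        stage="simulate", seed=cohort.config.seed, config=asdict(cohort.config),
        row_counts={"genomes": len(cohort.taxonomy)},
        output_hashes={str(p.relative_to(out_dir)): sha256_file(p) for p in sorted(paths.values())}
        | {"taxonomy.tsv": sha256_file(out_dir / "taxonomy.tsv")},
    )
    manifest.write(out_dir / "manifest.json")
    return cohort


def cmd_profile(
    fasta_dir: str | Path,
    out_path: str | Path,
    metadata: pd.DataFrame | None = None,
    genetic_code: int = 11,
    aggregate: str = "replicon",
) -> pd.DataFrame:
    """Profile every ``*.fasta`` CDS file in a directory into one TSV row per
    replicon (or per genome with ``aggregate="genome"``).

    ``metadata`` may carry a ``replicon_type`` column; replicons flagged as
    plasmids are excluded with a log line (plasmids are removed from the
    corpus by design).
    """
    fasta_dir = Path(fasta_dir)
    files = sorted(fasta_dir.glob("*.fasta"))
    if not files:
        raise EmptyInputError(f"no *.fasta files in {fasta_dir}")
    plasmids: set[str] = set()
    genome_of: dict[str, str] = {}
    if metadata is not None:
        key = "replicon_id" if "replicon_id" in metadata.columns else "genome_id"
        if "replicon_type" in metadata.columns:
            plasmids = set(
                metadata.loc[
                    metadata["replicon_type"].str.lower() == "plasmid", key
                ].astype(str)
            )
        if "genome_id" in metadata.columns and key == "replicon_id":
            genome_of = dict(zip(metadata["replicon_id"].astype(str), metadata["genome_id"].astype(str)))
    profiles, metrics = [], []
    merged: dict[str, object] = {}
    for path in files:
        rid = path.stem
        if rid in plasmids:
            logger.info("excluding plasmid replicon %s", rid)
            continue
        gid = genome_of.get(rid, rid)
        cds_set = read_cds_fasta(path, genome_id=gid, replicon_id=rid)
        if aggregate == "genome":
            if gid in merged:
                merged[gid].cds.extend(cds_set.cds)  # type: ignore[attr-defined]
            else:
                merged[gid] = cds_set
        else:
            cds_set.genome_id = rid
            p, m = profile_genome(cds_set, genetic_code=genetic_code)
            profiles.append(p)
            metrics.append(m)
    if aggregate == "genome":
        for cds_set in merged.values():
            p, m = profile_genome(cds_set, genetic_code=genetic_code)  # type: ignore[arg-type]
            profiles.append(p)
            metrics.append(m)
    if not profiles:
        raise EmptyInputError("no replicons left after exclusions")
    df = profiles_to_frame(profiles, metrics)
    write_results_tsv(df, out_path)
    return df


def cmd_analyze(
    profiles: pd.DataFrame,
    taxonomy: pd.DataFrame,
    config: AnalysisConfig | None = None,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> dict:
    """Run every analysis stage on a profile table.

    Returns a dict of fitted objects; writes one sub-directory per analysis
    plus a run manifest when ``out_dir`` is given.  Stages whose
    preconditions fail (too few genomes or groups) are skipped with an
    explicit notice recorded under ``skipped``.
    """
    config = config or AnalysisConfig()
    missing = set(profiles.index) - set(taxonomy["genome_id"])
    if missing:
        raise ContractViolation(f"taxonomy missing rows for genomes: {sorted(missing)[:5]}")
    tax = taxonomy[taxonomy["genome_id"].isin(profiles.index)].reset_index(drop=True)
    results: dict = {"skipped": {}}
    at = profiles["at_fraction"]
    phylum = tax.set_index("genome_id")["phylum"].reindex(profiles.index)

    data = profiles.reset_index()[
        ["genome_id", "at_fraction", "aaub", "cub", "kl", "genome_size"]
    ]
    rs = RandomStructure(levels=tuple(config.hierarchy), slope_on=config.slope_on)

    # multivariate stages
    if len(profiles) >= 3:
        for label, cols in (("aa", AA_COLUMNS), ("codon", CODON_COLUMNS)):
            pca = pca_correlation(profiles[cols], at_vector=at)
            r2_at, p_at = regress_component_on_covariate(pca.scores["PC1"], at)
            r2_ph, p_ph = regress_component_on_covariate(pca.scores["PC2"], phylum)
            results[f"pca_{label}"] = {
                "pca": pca, "pc1_at_r2": r2_at, "pc1_at_p": p_at,
                "pc2_phylum_r2": r2_ph, "pc2_phylum_p": p_ph,
            }
    else:
        results["skipped"]["pca"] = "fewer than 3 genomes"
    if len(profiles) >= 2:
        dend = cluster_genomes(profiles[AA_COLUMNS])
        annot = pd.DataFrame({"at_fraction": at, "phylum": phylum})
        ordered, side = export_heatmap_inputs(profiles[AA_COLUMNS], dend, annot)
        results["clustering"] = {"dendrogram": dend, "ordered": ordered, "annotations": side}
    else:
        results["skipped"]["clustering"] = "fewer than 2 genomes"

    # %AT on the 64 codon frequencies
    try:
        results["at_on_codons"] = fit_at_on_codons(profiles)
    except (DegenerateModelError, ContractViolation) as exc:
        results["skipped"]["at_on_codons"] = str(exc)

    # AAUB phylum ANOVA
    try:
        results["anova"] = fit_anova_aaub_phylum(profiles["aaub"], tax)
    except (DegenerateModelError, ContractViolation) as exc:
        results["skipped"]["anova"] = str(exc)

    # GAM (AAUB ~ s(CUB)) and its GAMM counterpart
    gam_spec = ModelSpec(
        response="aaub", smooth_terms=[("cub", config.basis_dim)], method=config.method
    )
    try:
        results["gam_aaub_cub"] = fit_gam(gam_spec, data)
    except (DegenerateModelError, ContractViolation) as exc:
        results["skipped"]["gam_aaub_cub"] = str(exc)
    n_groups = tax["phylum"].nunique()
    if n_groups >= 2:
        gamm_spec = ModelSpec(
            response="aaub", smooth_terms=[("cub", config.basis_dim)],
            random_structure=rs, method=config.method,
        )
        try:
            results["gamm_aaub_cub"] = fit_gamm(gamm_spec, data, tax)
        except (DegenerateModelError, ContractViolation) as exc:
            results["skipped"]["gamm_aaub_cub"] = str(exc)

        # KL ~ s(%AT) + AAUB, with and without random effects, plus AIC
        kl_spec = ModelSpec(
            response="kl", linear_terms=["aaub"],
            smooth_terms=[("at_fraction", config.basis_dim)],
            random_structure=rs, method=config.method,
        )
        try:
            kl_gamm = fit_gamm(kl_spec, data, tax)
            kl_gam = fit_gam(
                ModelSpec(response="kl", linear_terms=["aaub"],
                          smooth_terms=[("at_fraction", config.basis_dim)],
                          method=config.method),
                data,
            )
            results["kl_gamm"] = kl_gamm
            results["kl_gam"] = kl_gam
            results["aic_comparison"] = compare_aic(
                kl_gamm, kl_gam, name_a="random_effects", name_b="fixed_only"
            )
        except (DegenerateModelError, ContractViolation) as exc:
            results["skipped"]["kl_gamm"] = str(exc)

        try:
            results["kl_vs_size"] = fit_kl_vs_size(data, tax, random_structure=rs)
        except (DegenerateModelError, ContractViolation) as exc:
            results["skipped"]["kl_vs_size"] = str(exc)
    else:
        results["skipped"]["gamm_stages"] = "insufficient groups (need >= 2 phyla)"

    for stage, reason in results["skipped"].items():
        logger.warning("stage %s skipped: %s", stage, reason)

    if out_dir is not None:
        _write_analysis(results, profiles, Path(out_dir), config, seed)
    return results


def _model_tables(fit) -> dict[str, pd.DataFrame]:
    out = {"coefficients": fit.fixed, "random_sd": fit.random_sd}
    for var, sm_est in fit.smooths.items():
        out[f"smooth_{var}"] = sm_est.curve
    out["summary"] = pd.DataFrame(
        {"value": {"aic": fit.aic, "loglik": fit.loglik, "sigma2": fit.sigma2,
                   "r_squared": fit.r_squared, "edf_total": fit.edf_total,
                   "n_obs": fit.n_obs, "converged": float(fit.converged)}}
    )
    return out


def _write_analysis(results, profiles, out_dir: Path, config, seed) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    counts = {"genomes": len(profiles)}
    for label in ("aa", "codon"):
        key = f"pca_{label}"
        if key in results:
            d = out_dir / key
            d.mkdir(exist_ok=True)
            pca = results[key]["pca"]
            write_results_tsv(pca.scores, d / "scores.tsv")
            write_results_tsv(pca.loadings, d / "loadings.tsv")
            write_results_tsv(
                pd.DataFrame({"variance_fraction": pca.variance_fraction},
                             index=pca.scores.columns), d / "variance.tsv",
            )
    if "clustering" in results:
        d = out_dir / "clustering"
        d.mkdir(exist_ok=True)
        (d / "dendrogram.nwk").write_text(to_newick(results["clustering"]["dendrogram"]) + "\n")
        write_results_tsv(results["clustering"]["ordered"], d / "heatmap_matrix.tsv")
        write_results_tsv(results["clustering"]["annotations"], d / "heatmap_annotations.tsv")
    if "at_on_codons" in results:
        d = out_dir / "at_on_codons"
        d.mkdir(exist_ok=True)
        write_results_tsv(results["at_on_codons"].coefficients, d / "coefficients.tsv")
    if "anova" in results:
        d = out_dir / "anova_aaub_phylum"
        d.mkdir(exist_ok=True)
        write_results_tsv(results["anova"].group_means, d / "phylum_means.tsv", index=False)
    for key in ("gam_aaub_cub", "gamm_aaub_cub", "kl_gamm", "kl_gam", "kl_vs_size"):
        if key in results:
            d = out_dir / key
            d.mkdir(exist_ok=True)
            for name, table in _model_tables(results[key]).items():
                write_results_tsv(table, d / f"{name}.tsv")
    if "aic_comparison" in results:
        cmp_ = results["aic_comparison"]
        (out_dir / "aic_comparison.json").write_text(json.dumps(asdict(cmp_), indent=2) + "\n")
    manifest = RunManifest(
        stage="analyze", seed=seed,
        config=asdict(config) if config else {},
        row_counts=counts,
        output_hashes={
            str(p.relative_to(out_dir)): sha256_file(p)
            for p in sorted(out_dir.rglob("*.tsv"))
        },
    )
    manifest.write(out_dir / "manifest.json")


__all__ = [
    "AnalysisConfig", "RunManifest", "CohortConfig",
    "cmd_simulate", "cmd_profile", "cmd_analyze",
    "profiles_to_frame", "PROFILE_COLUMNS", "NUC_COLUMNS", "CODON_COLUMNS", "AA_COLUMNS",
    "read_taxonomy_table",
]
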