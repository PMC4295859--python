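"""End-to-end pipeline driver: simulate/load -> preprocess -> trend ->
overlap -> enrichment, with a run manifest.

All randomness flows from the seeds held in the :class:`RunConfig`; no
stage touches global random state, so two runs with the same config are
byte-identical apart from timestamps (which only the manifest carries).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import yaml

from . import io as dio
from .gsea import permutation_test, report_enriched
from .overlap import direction_concordance, overlap_select, top_k_lists
from .preprocess import average_hybridizations, quantile_normalize
from .synthetic import (
    AcuteDesign,
    ChronicDesign,
    generate_acute_experiment,
    generate_chronic_experiment,
    generate_gmt_catalog,
)
from .trend import acute_sigma_z, chronic_ttest_rank

__version__ = "0.1.0"


@dataclass
class RunConfig:
    """Stage parameters for a full synthetic-study run."""

    # selection / reporting constants
    k: int = 50
    min_membership: int = 3
    n_perm: int = 1000
    fdr_max: float = 0.10
    p_max: float = 0.025
    weight_p: float = 1.0
    baseline_time: int = 6
    # study layout
    drugs: tuple = ("bleomycin", "cisplatin")
    n_genes: int = 1000
    n_trend_genes: int = 20
    effect_size_log2: float = 1.0
    noise_sd_log2: float = 0.5
    replicates_per_group: int = 2
    hybridizations_per_specimen: int = 4
    # the chronic screen competes single t-tests against a top-k cut, so the
    # demo powers it with more independent arms than the acute dose ladder
    replicates_per_arm: int = 6
    # enrichment catalog
    n_sets: int = 169
    set_size_range: tuple = (10, 60)
    # seeds
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")
        for name in ("fdr_max", "p_max"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.min_membership < 1:
            raise ValueError("min_membership must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("drugs", "set_size_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run the full synthetic study and write its report bundle.

    One acute and one chronic experiment is simulated per drug, with the
    same planted candidate genes across all settings (their noise differs
    by per-setting seeds); each is normalized, trend-ranked and reduced to
    its top-k list; the lists are overlapped at the membership threshold;
    and the first drug's acute ranking is screened against a random
    gene-set catalog carrying one planted set.  Returns the report bundle
    as a dict of DataFrames/objects and writes TSVs plus a manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng_seed = np.random.SeedSequence(config.seed)
    setting_seeds = rng_seed.generate_state(2 * len(config.drugs) + 2) % (2**31)

    lists, rankings, truths = [], {}, {}
    for d_idx, drug in enumerate(config.drugs):
        acute = AcuteDesign(
            n_genes=config.n_genes,
            n_trend_genes=config.n_trend_genes,
            effect_size_log2=config.effect_size_log2,
            noise_sd_log2=config.noise_sd_log2,
            replicates_per_group=config.replicates_per_group,
            hybridizations_per_specimen=config.hybridizations_per_specimen,
            drug=drug,
            seed=int(setting_seeds[2 * d_idx]),
            spike_seed=config.seed,
        )
        matrix, truth = generate_acute_experiment(acute)
        matrix = average_hybridizations(quantile_normalize(matrix))
        trend = acute_sigma_z(matrix)
        setting = f"{drug}_acute"
        rankings[setting] = trend
        truths[setting] = truth
        lists.append(top_k_lists(trend, config.k, "acute", setting=setting))

        chronic = ChronicDesign(
            n_genes=config.n_genes,
            n_affected_genes=config.n_trend_genes,
            effect_size_log2=config.effect_size_log2,
            noise_sd_log2=config.noise_sd_log2,
            replicates_per_arm=config.replicates_per_arm,
            drug=drug,
            seed=int(setting_seeds[2 * d_idx + 1]),
            spike_seed=config.seed,
        )
        cmatrix, ctruth = generate_chronic_experiment(chronic)
        cmatrix = quantile_normalize(cmatrix)
        ctrend = chronic_ttest_rank(cmatrix)
        setting = f"{drug}_chronic"
        rankings[setting] = ctrend
        truths[setting] = ctruth
        lists.append(top_k_lists(ctrend, config.k, "chronic", setting=setting))

    report = overlap_select(lists, m=config.min_membership)
    concordance = direction_concordance(report, lists)

    # enrichment on the first acute ranking, planting the spiked up-genes
    first_acute = f"{config.drugs[0]}_acute"
    truth = truths[first_acute]
    planted = truth.genes.loc[truth.genes["direction"] > 0, "gene"].tolist()
    ranking = rankings[first_acute]["sigma_z"]
    catalog = generate_gmt_catalog(
        n_sets=config.n_sets,
        size_range=config.set_size_range,
        n_genes=config.n_genes,
        planted_set=planted if len(planted) >= 5 else None,
        seed=int(setting_seeds[-2]),
        gene_ids=list(ranking.index),
    )
    enrichment = permutation_test(
        ranking, catalog, n_perm=config.n_perm, seed=int(setting_seeds[-1]),
        weight_p=config.weight_p,
    )
    enriched = report_enriched(enrichment, fdr_max=config.fdr_max, p_max=config.p_max)

    # -- write bundle --------------------------------------------------------
    for setting, trend in rankings.items():
        dio.write_trend_table(trend, out_dir / f"trend_{setting}.tsv")
    for lst in lists:
        dio.write_ranked_list(lst, out_dir / f"top{config.k}_{lst.setting}.tsv")
    report.membership.rename_axis("gene").to_csv(out_dir / "overlap_membership.tsv", sep="\t")
    (out_dir / "candidates.txt").write_text("\n".join(report.candidates) + "\n")
    enrichment.to_csv(out_dir / "enrichment.tsv", sep="\t", index=False)
    enriched.to_csv(out_dir / "enrichment_reported.tsv", sep="\t", index=False)
    dio.write_manifest(
        out_dir / "manifest.json",
        version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
        config=asdict(config),
        candidates=report.candidates,
        n_enriched=len(enriched),
    )
    return {
        "lists": lists,
        "overlap": report,
        "concordance": concordance,
        "rankings": rankings,
        "truths": truths,
        "enrichment": enrichment,
        "enriched": enriched,
    }
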