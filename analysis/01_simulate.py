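"""Generate the synthetic study datasets.

Simulates, with fixed seeds, everything the downstream analyses consume:
per-drug acute (dose ladder x 6/24/48 h) and chronic (IC10 vs control,
day 30) expression experiments with planted trend genes, a 41-patient
plasma panel over the BEP course schedule, and a random KEGG-sized
gene-set catalog.  Full matrices land in scratch/ (regenerable); the truth
tables and dataset shapes land in results/.
"""

from pathlib import Path

from dosetrend import (
    AcuteDesign,
    ChronicDesign,
    PlasmaDesign,
    generate_acute_experiment,
    generate_chronic_experiment,
    generate_gmt_catalog,
    generate_plasma_panel,
)
from dosetrend import io as dio

SEED = 20150115
ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results"


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    for d_idx, drug in enumerate(("bleomycin", "cisplatin")):
        acute = AcuteDesign(n_genes=1000, n_trend_genes=20, drug=drug,
                            seed=SEED + d_idx, spike_seed=SEED)
        matrix, truth = generate_acute_experiment(acute)
        dio.write_expression(matrix, SCRATCH / f"{drug}_acute_matrix.tsv",
                             SCRATCH / f"{drug}_acute_design.tsv")
        truth.genes.to_csv(RESULTS / f"truth_{drug}_acute.tsv", sep="\t", index=False)
        print(f"{drug} acute: {matrix.n_genes} genes x {matrix.n_samples} samples, "
              f"{len(truth.genes)} planted trend genes")

        chronic = ChronicDesign(n_genes=1000, n_affected_genes=20, drug=drug,
                                replicates_per_arm=6, seed=SEED + 10 + d_idx,
                                spike_seed=SEED)
        cmatrix, ctruth = generate_chronic_experiment(chronic)
        dio.write_expression(cmatrix, SCRATCH / f"{drug}_chronic_matrix.tsv",
                             SCRATCH / f"{drug}_chronic_design.tsv")
        ctruth.genes.to_csv(RESULTS / f"truth_{drug}_chronic.tsv", sep="\t", index=False)
        print(f"{drug} chronic: {cmatrix.n_genes} genes x {cmatrix.n_samples} samples "
              f"(same planted genes across settings)")

    panel, truth = generate_plasma_panel(PlasmaDesign(seed=SEED))
    dio.write_plasma(panel, SCRATCH / "plasma.csv", SCRATCH / "plasma_metadata.csv")
    print(f"plasma panel: {panel.data['patient_id'].nunique()} patients x "
          f"{len(panel.schedule)} timepoints x {len(panel.markers)} markers")

    catalog = generate_gmt_catalog(n_sets=169, size_range=(10, 60), n_genes=1000,
                                   seed=SEED + 99)
    dio.write_gmt(catalog, SCRATCH / "catalog.gmt")
    print(f"gene-set catalog: {len(catalog)} sets")


if __name__ == "__main__":
    main()
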