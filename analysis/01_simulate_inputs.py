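"""Generate all four synthetic input families with known ground truth.

Writes a TMA core-scoring table, one example two-channel fluorescence
field (TIFF + masks), an expression cohort with survival annotations,
and a qPCR knockdown plate.  Every downstream driver can re-derive
these from the same seed; this script materializes them for inspection.
"""

import argparse
from pathlib import Path

from ccapipe import io, synthetic


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results/simulated"))
    args = parser.parse_args()
    meta = io.provenance(args.seed)
    out = args.out

    obs, truth = synthetic.generate_tma_cohort(synthetic.TMACohortSpec(seed=args.seed))
    io.write_table(obs, out / "tma_observations.csv", meta)
    io.write_table(truth, out / "tma_truth.csv", meta)
    print(f"TMA cohort: {truth['tumor_id'].nunique()} tumors, {len(obs)} core observations")

    field = synthetic.generate_if_field(synthetic.IFFieldSpec(seed=args.seed), "example")
    io.write_field_tiff(field.channels, out / "field_example.tiff")
    io.write_mask_tiff(field.nuclear_mask, out / "field_example_nuclei.tiff")
    io.write_mask_tiff(field.cytoplasm_mask, out / "field_example_cytoplasm.tiff")
    print(f"IF field: {field.n_cells} cells, planted n/c ratio {field.true_ratio}")

    spec = synthetic.ExpressionCohortSpec(seed=args.seed)
    matrix, annotations, survival = synthetic.generate_expression_cohort(spec)
    io.write_table(matrix.reset_index(), out / "expression_counts.tsv", meta)
    io.write_table(annotations, out / "expression_annotations.tsv", meta)
    io.write_table(survival, out / "survival.tsv", meta)
    n_cin = int(annotations["planted_cin"].sum())
    print(
        f"Expression cohort: {spec.n_tumors} tumors + {spec.n_normals} normals, "
        f"{len(matrix)} genes, {n_cin} planted high-CIN tumors"
    )

    plate = synthetic.generate_knockdown_plate(synthetic.KnockdownPlateSpec(seed=args.seed))
    io.write_table(plate, out / "knockdown_plate.csv", meta)
    print(f"Knockdown plate: {plate['gene'].nunique()} genes x {plate['condition'].nunique()} conditions")


if __name__ == "__main__":
    main()
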