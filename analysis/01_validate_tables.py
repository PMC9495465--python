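#!/usr/bin/env python
"""Desk validation of the packaged result tables.

Recomputes the FIF arithmetic (impact x 1/HR) and the affinity impact
implied by the printed RBS pairs for all 27 scored-call rows, flags the two
sign-inconsistent cells, and checks the headline counts (gene panel totals,
distinct variants/genes/cell lines, GWAVA-deleterious fraction).

Writes results/table_checks.tsv and prints a short narrative.
"""
from pathlib import Path

from rsnpscan.confirm import summarize_predictions
from rsnpscan.scoring import affinity_impact, fif_of
from rsnpscan.synthdata import table_fixtures

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    panel, calls, evidence = table_fixtures()

    rows = ["gene\trsid\ttf\tprinted_fif\trecomputed_fif\tfif_exact"
            "\tprinted_impact\timpact_from_rbs\timpact_dev_pp\tflagged"]
    exact = 0
    worst_dev = 0.0
    for c in calls:
        fif = round(fif_of(c.affinity_impact_pct, c.hr), 2)
        is_exact = fif == c.fif
        exact += is_exact
        impact = affinity_impact(c.rbs_major, c.rbs_minor)
        dev = abs(abs(impact) - abs(c.affinity_impact_pct))
        worst_dev = max(worst_dev, dev)
        rows.append(f"{c.gene_symbol}\t{c.rsid}\t{c.tf_name}\t{c.fif:.2f}\t{fif:.2f}"
                    f"\t{is_exact}\t{c.affinity_impact_pct:.2f}\t{impact:.2f}"
                    f"\t{dev:.2f}\t{c.sign_inconsistent}")
    OUT.mkdir(exist_ok=True)
    (OUT / "table_checks.tsv").write_text("\n".join(rows) + "\n")

    summary = summarize_predictions(calls, evidence)
    flagged = [c for c in calls if c.sign_inconsistent]
    print(f"FIF arithmetic exact on {exact}/{len(calls)} rows; "
          f"{len(flagged)} flagged sign-inconsistent cells "
          f"({', '.join(sorted({c.rsid for c in flagged}))}) match in magnitude")
    print(f"worst |impact| deviation from printed RBS pairs: {worst_dev:.2f} pp")
    print(f"panel: {len(panel)} genes, {sum(g.n_common_snps for g in panel)} common SNPs")
    print(f"calls: {summary.n_rsnps} distinct rSNPs in {summary.n_genes} genes "
          f"over {summary.n_cell_lines} cell lines")
    print(f"GWAVA-deleterious fraction: {summary.gwava_deleterious_fraction:.1%}")


if __name__ == "__main__":
    main()
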