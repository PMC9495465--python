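#!/usr/bin/env python
"""Aggregate the external-evidence table over the published calls.

Applies the any-evidence confirmation rules (GWAVA/FunSeq2 deleteriousness,
DeepSEA eQTL probability >= 0.5, GTEx m-value > 0.9, Ensembl effect size
present, expression at least 'low' in the relevant cell line) to each of
the seven called variants and writes the roll-up to
results/confirmation_summary.tsv.
"""
from pathlib import Path

from rsnpscan.confirm import confirm_rsnp, summarize_predictions
from rsnpscan.synthdata import table_fixtures

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    _, calls, evidence = table_fixtures()
    summary = summarize_predictions(calls, evidence)
    print(summary.to_text())

    by_rsid: dict[str, list] = {}
    for ev in evidence:
        by_rsid.setdefault(ev.rsid, []).append(ev)
    rows = ["rsid\tconfirmed\ttags"]
    for rsid in sorted(by_rsid):
        ok, tags = confirm_rsnp(by_rsid[rsid])
        rows.append(f"{rsid}\t{ok}\t{','.join(tags)}")
    rows.append("")
    rows.append(summary.to_tsv().rstrip("\n"))
    (ROOT / "results").mkdir(exist_ok=True)
    (ROOT / "results" / "confirmation_summary.tsv").write_text("\n".join(rows) + "\n")


if __name__ == "__main__":
    main()
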