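"""Classify riboswitch-regulated operons against the gene-function catalogue.

Loads the packaged table of published riboswitch-regulated operons and counts
lysine biosynthesis, transporter, catabolic, hypothetical and unrelated genes
in each, reproducing the compositions the operon table reports.
"""

import riboregulon as rb

catalog = rb.FunctionCatalog.default()
df = rb.load_table1_operons()

for _, row in df.head(8).iterrows():
    comp = rb.operon_composition(row["genes"], catalog)
    counts = ", ".join(f"{k}={v}" for k, v in sorted(comp.counts.items()))
    print(f"{row['species']:<38} {'-'.join(row['genes']):<60} "
          f"total={comp.total} ({counts})")

big = rb.operon_composition(
    ["lysC", "asd", "dapA", "dapB", "dapD", "amino hydrolase", "alr", "lysA"],
    catalog)
print(f"\nThe largest operon has {big.total} genes of which "
      f"{big.counts['biosynthesis']} belong to the DAP lysine-biosynthesis "
      "pathway; the amino hydrolase and alanine racemase are functionally "
      "unrelated insertions.")
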