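"""Hypergeometric over-representation of gene sets in a DTG list.

Gene sets come from GMT files; the universe defaults to all genes that
survive the expression filters; p-values are upper-tail hypergeometric
with Benjamini-Hochberg adjustment across sets.
"""

from polytome.enrichment import GeneSetCollection, ora_hypergeometric

universe = {f"g{i:03d}" for i in range(400)}
ribosome = {f"g{i:03d}" for i in range(0, 40)}       # a 'ribosomal protein' set
metabolism = {f"g{i:03d}" for i in range(40, 140)}   # an unrelated set

# a query in which the ribosome set is strongly over-represented
query = {f"g{i:03d}" for i in range(0, 30)} | {f"g{i:03d}" for i in range(200, 220)}

collection = GeneSetCollection({"ribosome": ribosome, "metabolism": metabolism})
result = ora_hypergeometric(query, collection, universe)
print(result[["set_size", "overlap", "expected", "enrichment_ratio", "p", "adj_p"]]
      .to_string(float_format=lambda v: f"{v:.3g}"))
# 30 of the 50 query genes fall in the 40-gene ribosome set where 5 were
# expected: the kind of signal the translation-machinery sets show among
# glucose-upregulated transcripts.
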