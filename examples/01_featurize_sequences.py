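"""Featurize a handful of ODN sequences and inspect the descriptors.

Builds the positional fingerprint dictionary from a tiny labelled set,
then prints the worked motif-distance examples and the feature row of one
sequence.
"""

from odnscreen import (
    OdnRecord,
    assign_labels,
    build_dictionary,
    count_nucleotides,
    distance_descriptors,
    featurize,
    motif_positions,
    split_by_label,
)

S1 = "TATGCGTTCGTACTTGATCTGAC"
S2 = "TGCTTTCTTGTCGTGCGGGCTGT"

# The CG dinucleotide pairs in both sequences are 4 steps apart, but the
# d_CG2_1 descriptor adds the number of nucleotides before the second
# occurrence, pinning each pair to its absolute location.
for name, seq in (("S1", S1), ("S2", S2)):
    pos = motif_positions(seq, "CG")
    d21 = distance_descriptors(seq, "CG")[0]
    print(f"{name}: CG at {pos}, gap {pos[1] - pos[0]}, d_CG2_1 = {d21}")

records = assign_labels(
    [
        OdnRecord("a1", "CGGCCGTACGGCATCGGCCGTACG", 0.71),
        OdnRecord("a2", "GGCCGTTACGGCCGTAGGCCGTAC", 0.55),
        OdnRecord("b1", "TTTATCTATTTATCTATTTATCTA", 0.12),
        OdnRecord("b2", "ATATTCTTATATTCTTATATTCTT", 0.21),
    ]
)
high, low = split_by_label(records)
dictionary = build_dictionary(high, low, threshold=0.10)
print(f"\nfingerprint dictionary: {len(dictionary)} positional tokens, "
      f"e.g. {dictionary.names[:5]}")

X = featurize(records, dictionary)
print(f"feature matrix: {X.shape[0]} ODNs x {X.shape[1]} features")
print("first row (nucleotide counts then descriptors):")
print(X.iloc[0, :12].to_string())
print("\nNucleotide counts of S1:", count_nucleotides(S1))
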