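"""Extract screening rules for the published drug groups with a CART tree.

Grows a Gini classification tree on the published 8x21 ratio matrix with
the published 6x1 unit numbers as class labels, then prints the rule for
each leaf.  The three split thresholds (2.6%, 1.2%, 17%) are the
midpoints between adjacent observed category shares.
"""

from irae_som import extract_rules, grow, load_category_matrix, load_unit_labels

matrix = load_category_matrix()
units = load_unit_labels()
tree = grow(matrix, [units[d] for d in matrix.drugs])

print("splits:")
for node in tree.internal_nodes():
    print(f"  {node.split_feature} at {node.threshold:.6g} "
          f"(node of {len(node.members)} drugs)")

print("\nrules (one per leaf):")
for rule in extract_rules(tree):
    print(" ", rule)
# reading: a drug whose type 1 diabetes mellitus share of all-drug
# category cases is below 2.6% falls in the low-report-volume group
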