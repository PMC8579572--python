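"""Tree-shape statistics on the five-tip worked example.

Builds the small structured tree with one migration node, prints all eleven
statistics, and shows the Newick serialisation with deme comments.
"""

from phylostruct import compute_statistics_record, newick_string, worked_example_tree

tree = worked_example_tree()
print("Newick:", newick_string(tree))

rec = compute_statistics_record(tree)
for name, value in rec.as_dict().items():
    print(f"  {name:>18}: {value}")

# The two cherries are (1,2) and (4,5); the migration node on the path to
# tips 1 and 2 deepens them, which is why the Sackin index is 14 (its
# caterpillar maximum for five tips, hence normalised Sackin = 1) while the
# Colless index stays low (2): depth-type and balance-type statistics react
# differently to migration events.
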