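"""Annotate an MS2/MS3 fragmentation tree by neutral-loss search.

The polyketide oxasetin (C21H29NO4, [M+H]+ at m/z 360.2166) fragments in
MS2 to 316.1897 and 272.1633; re-isolating 272.1633 gives three MS3 ions.
Each fragment is matched against every subformula of the precursor ion; the
complementary neutral losses accumulate along the tree.
"""

from mycomet import FragmentObservation, build_tree, parse_formula

precursor_mz = 360.2166
formula = parse_formula("C21H29NO4")

ms2 = [FragmentObservation(2, precursor_mz, mz) for mz in (316.1897, 272.1633)]
ms3 = {
    272.1633: [
        FragmentObservation(3, 272.1633, mz) for mz in (228.1366, 198.0912, 172.0733)
    ]
}

tree = build_tree(precursor_mz, formula, ms2, ms3, tolerance_mda=5.0)

print(f"precursor [M+H]+ {precursor_mz}  ion composition {tree.precursor_ion.composition}")
for node in tree.all_nodes():
    best = node.best
    path = " - ".join(f.hill() for f in best.cumulative_losses)
    print(
        f"  MS{node.observation.ms_level}  m/z {node.observation.fragment_mz:9.4f}"
        f"  [M+H-{path}]+  ion {best.fragment_formula.hill():<10}"
        f"  {best.mass_error_mda:+.2f} mDa"
    )

# Each row is one fragment: the loss path (e.g. C4H8O2 then C4H10O), the
# retained ion composition and its mass error. All losses are small
# even-electron neutrals, consistent with the proposed structure.
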