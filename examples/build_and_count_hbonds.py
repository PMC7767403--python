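"""Count Watson-Crick hydrogen bonds before and after the point mutation.

Builds an idealized B-DNA duplex carrying the wild-type A.T pair at the
regulatory site, swaps it for the variant C.G pair, and detects hydrogen
bonds with the strict geometric criteria (donor-acceptor < 3.0 A,
H-donor-acceptor angle < 20 deg). A G.C pair contributes three bonds,
an A.T pair two, so the mutation adds exactly one bond at the site.
"""

from snpbindshift import assign_donors_acceptors, build_duplex, detect_hbonds, mutate_pair


def count_bonds(structure):
    table = assign_donors_acceptors(structure)
    return len(detect_hbonds(structure.coordinates(), table))


wild_type = build_duplex("GCGAAGC")  # site 4 holds the A.T pair
mutant = mutate_pair(wild_type, position=4, new_pair="CG")

print(f"wild-type duplex ({wild_type.n_atoms} atoms): {count_bonds(wild_type)} H-bonds")
print(f"mutant duplex   ({mutant.n_atoms} atoms): {count_bonds(mutant)} H-bonds")
print("difference: +1 bond at the mutated pair (A.T forms 2, C.G forms 3)")
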