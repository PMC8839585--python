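"""Select fluorophore-conjugation sites from apo/bound dihedral ensembles.

Builds a synthetic 50-residue protein in which three residues shift their
backbone conformational microstates upon ligand binding (occupancy shifts of
0.3, 0.6 and 1.0), scores every residue by the change in its Ramachandran
histogram, and ranks candidates.  A complete microstate shift gives the
maximum raw difference of 2 and a normalized score of 1; partial shifts
score proportionally (raw difference ~ 2 x shift).
"""

import cinc

apo, bound, site, _ = cinc.synth_protein_system(
    n_residues=50,
    signal_residues={10: 0.3, 25: 0.6, 40: 1.0},
    frames=5000, n_replicates=3, seed=42,
    binding_site=[20, 21],  # excluded from candidacy, still scored
)

records = cinc.score_states(apo, bound, ligand_state="ligand",
                            binding_site=site)
table = cinc.aggregate(records)
ranked = cinc.rank_candidates(table, binding_site=site, n=5)

print("rank  residue   mean score   raw diff (mean over replicates)")
raw = dict(zip(table.per_ligand["residue"], table.per_ligand["raw_diff_mean"]))
for row in ranked.itertuples():
    print(f"{row.rank:>4}  {str(row.residue):<8}  {row.cross_mean:10.4f}"
          f"   {raw[row.residue]:.4f}")
print("\nThe three engineered residues lead the ranking in shift order;")
print("every other residue's score reflects pure sampling noise.")
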