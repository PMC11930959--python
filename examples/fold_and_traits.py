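"""Fold one RNA replicator and derive its full phenotype.

Builds the genotype->phenotype map for a single sequence: MFE secondary
structure, degradation probability, foldedness, replicability and the
enzymatic activity vector scored against the packaged motif rules.
"""

import riboworld as rw

chem = rw.Chemistry(rw.RuleTable.default(A=3))

# a designed hairpin: 5-bp G:C stem around a 7-base loop whose centre
# reads AGC -> a full match of activity rule 1
rep = chem.replicator("GGGGGUUAGCUUCCCCC")

t = rep.traits
print("sequence       ", rep.sequence)
print("structure      ", rep.structure.dot_bracket)
print(f"dG_min          {t.dG_min:.2f} kcal/mol")
print(f"P_deg           {t.P_deg:.4f}   (per-update degradation probability)")
print(f"P_fold          {t.P_fold:.4f}   (fraction of lifetime spent folded)")
print(f"R               {t.R:.4f}   (replication rate)")
print("activities     ", [round(float(a), 4) for a in t.activities])
print("classification ", chem.classify(rep).label)

# The activity vector has one nonzero slot (rule 1): this strand is a
# specialist ribozyme.  Its reverse complement carries no motif, so the
# complementary strand is a functional parasite -- it contributes
# nothing to the metabolism yet is the template the specialist needs.
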