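"""Curation quality control on a deliberately flawed model.

Injects known flaws into the toy model (carbon-imbalanced reactions, exact
duplicates, a self-amplifying stoichiometrically inconsistent reaction),
then shows that the balance check, duplicate removal and consistency LP
recover exactly the injected ground truth, and that stepwise pruning keeps
the biomass optimum and the growth tasks intact.
"""

from sydicos import (
    ToySpec,
    elemental_balance,
    fba,
    make_default_tasks,
    make_toy_hepatic_model,
    perturb_model,
    prune_imbalanced,
    remove_duplicates,
    stoichiometric_consistency,
)

model = make_toy_hepatic_model()
perturbed, truth = perturb_model(
    model, ToySpec(seed=4, flaw_counts={"imbalanced": 2, "duplicate": 2,
                                        "inconsistent": 1}))
print(f"injected: {truth['imbalanced']} imbalanced, "
      f"{[d for d, _ in truth['duplicates']]} duplicates, "
      f"{truth['inconsistent_metabolites']} inconsistent")

found = [r.id for r in perturbed.reactions.values()
         if r.id != perturbed.objective
         and elemental_balance(r, perturbed.metabolites).status == "imbalanced"]
print(f"balance check finds: {found}")

deduped, dup_report = remove_duplicates(perturbed)
print(f"duplicate removal collapses: {dup_report.removed_duplicates}")

print(f"consistency LP flags: {sorted(stoichiometric_consistency(perturbed))}")

tasks = make_default_tasks()
ref = fba(perturbed).objective_value
pruned, report = prune_imbalanced(perturbed, tasks)
print(f"pruned {report.pruned}; biomass {ref:.4f} -> "
      f"{fba(pruned).objective_value:.4f} (unchanged), "
      f"all {len(tasks)} tasks still pass")
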