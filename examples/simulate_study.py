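"""Generate a small synthetic cross-linguistic study and look inside it.

A study bundles everything the analysis needs: checklist
administrations (one 0/1 response per child x item x measure),
child-directed-speech corpora, rating norms with missing cells, and
the mapping tables (inflections, polysemy, categories, translations).
"""

from lexacq import generate_study

study = generate_study(languages=["lang1", "lang2"], n_items=80,
                       n_children=200, n_utterances=3000, seed=42)

adm = study.administrations
print(f"{adm['child_id'].nunique()} children x {study.items.shape[0]} items "
      f"-> {len(adm)} responses across "
      f"{adm['language'].nunique()} languages and "
      f"{adm['measure'].nunique()} measures")
print("\nCategory composition (draws from 55/25/10/10% proportions):")
print(study.items["lexical_category"].value_counts().to_string())

by_age = (adm[adm["measure"] == "production"]
          .groupby("age_months")["value"].mean())
print("\nProportion of words produced by age (rises with age because the")
print("generating model has a positive standardized age effect):")
print(by_age.round(3).to_string())

norms = study.norms["lang1"]
print("\nMissing rating cells per column (MCAR, per configured rates):")
print(norms.isna().sum().to_string())
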