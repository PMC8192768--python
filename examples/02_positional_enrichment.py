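"""Per-position mutation enrichment: which positions are mutated more often
in toxic than in non-toxic light chains?

Plants one strong discriminative mutation and shows the Fisher exact
odds-ratio screen recovering it.
"""

import lctox as lx

spec = lx.SimSpec(
    n_tox=300, n_nox=300, background_sm_rate=0.03, seed=2,
    planted_effects=(lx.PlantedEffect(49, "A", p_tox=0.4, p_nox=0.05),),
)
records, truth = lx.generate_repertoire(spec)
germlines = {g.germline_id: g for g in spec.germline_set}
encodings, scheme = lx.encode_dataset(records, germlines)
labels = {r.sequence_id: r.label for r in records}

stats = lx.position_stats(lx.count_positions(encodings, labels))
parts = lx.classify_positions(stats, alpha=0.05)
print(f"positions enriched in tox: {sorted(parts['enriched_in_tox'])}")

top = max(stats, key=lambda s: 0 if s.nox_M == 0 else s.odds_ratio)
print(f"position {top.position}: tox {top.tox_M}/{top.tox_M + top.tox_NM} vs "
      f"nox {top.nox_M}/{top.nox_M + top.nox_NM} mutated, "
      f"OR={top.odds_ratio:.1f} (95% CI {top.ci95[0]:.1f}-{top.ci95[1]:.1f}), "
      f"p={top.p_value:.2e}")
# The planted position 49 dominates; background positions hover around OR 1.

tox_counts = [e.n_sm for e in encodings if labels[e.sequence_id] == "tox"]
nox_counts = [e.n_sm for e in encodings if labels[e.sequence_id] == "nox"]
t, p = lx.pdsm_compare(tox_counts, nox_counts)
print(f"somatic-mutation-count distributions (tox vs nox): t={t:.2f}, p={p:.3f}")
# A single planted position barely moves the per-sequence mutation count:
# the discriminative signal is positional, not a difference in mutation load.
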