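"""Score semantic typicality of interview answers against a TD reference.

Simulates answer embeddings for a cohort, builds the typically-developing
reference (component-wise median embedding per question over TD participants
aged 14-22), computes cosine typicality and Fisher-Z domain scores, and
compares the ASD and non-ASD groups on the narrative-type domains.
"""

from phenokit import semantic, synth

records, _ = synth.simulate_cohort(synth.CohortConfig(n_participants=1500), seed=11)
embeddings, _ = synth.simulate_embeddings(records, synth.EmbeddingSimConfig(), seed=11)

scores = semantic.semantic_table(embeddings, records)
scores = scores.merge(records[["participant_id", "asd"]], on="participant_id")

print("== mean domain typicality (cosine similarity to TD median) by ASD status ==")
domains = ["narrative_detail", "factual_memory", "thematic_understanding",
           "self_emotion", "preferences_negative"]
by_group = scores.groupby("asd")[domains].mean().T.rename(
    columns={0: "non-ASD", 1: "ASD"})
print(by_group.round(3).to_string())

ref = semantic.build_reference(embeddings, records)
q1 = embeddings[embeddings.question_id == 1]
winner = semantic.select_typical_answer(q1, ref.vector(1))
print(f"\nmost typical answer to question 1: participant {winner}")
print("\nLower typicality in the ASD column on narrative-type domains")
print("(narrative_detail, thematic_understanding, self_emotion) reflects the")
print("generative ASD-specific noise increase; the other domains differ only")
print("by sampling noise.")
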