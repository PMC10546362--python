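"""Extract PI-RADS scores and the significant-finding count from report text.

n_sig — the number of PI-RADS >= 4 findings in a report — is the only
piece of clinical information the pseudo-labeling pipeline needs.
"""

from rgpl import extract_scores

reports = {
    "positive": "Lesion 1: peripheral zone, 14 mm, PI-RADS 4.\nLesion 2: transition zone, 9 mm, PI-RADS 2.",
    "negative": "No suspicious focal lesions. Overall PI-RADS category: 2.",
    "amended": "Lesion 1: PI-RADS 3.\nAddendum: on review, Lesion 1: PI-RADS 5.",
    "unparseable": "Follow-up study; stable appearance compared with prior examination.",
}

for name, text in reports.items():
    f = extract_scores(text, dialect="structured_en", exam_id=name)
    print(f"{name:12s} status={f.status:12s} scores={list(f.scores)} n_sig={f.n_sig}")

# n_sig counts scores >= 4; the amended report shows the addendum overriding
# the body score; the unparseable report would be excluded from pseudo-labeling.
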