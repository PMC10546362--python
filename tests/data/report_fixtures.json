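[
  {
    "name": "two_lesions_one_significant",
    "dialect": "structured_en",
    "text": "Lesion 1: PI-RADS 4. Lesion 2: PI-RADS 2.",
    "scores": [4, 2],
    "n_sig": 1,
    "status": "parsed"
  },
  {
    "name": "empty_report",
    "dialect": "structured_en",
    "text": "",
    "scores": [],
    "n_sig": 0,
    "status": "unparseable"
  },
  {
    "name": "dutch_colon_no_hyphen",
    "dialect": "structured_en",
    "text": "Laesie 1 in de perifere zone, 14 mm. PIRADS: 5",
    "scores": [5],
    "n_sig": 1,
    "status": "parsed"
  },
  {
    "name": "split_score_counts_once_higher",
    "dialect": "structured_en",
    "text": "Lesion 1: transition zone, PI-RADS 4/5.",
    "scores": [5],
    "n_sig": 1,
    "status": "parsed"
  },
  {
    "name": "addendum_overrides_body",
    "dialect": "structured_en",
    "text": "Lesion 1: PI-RADS 3. Lesion 2: PI-RADS 4.\nAddendum: on review, Lesion 1: PI-RADS 5.",
    "scores": [5, 4],
    "n_sig": 2,
    "status": "parsed"
  },
  {
    "name": "addendum_adds_new_lesion",
    "dialect": "structured_en",
    "text": "Lesion 1: PI-RADS 4.\nAddendum: additional Lesion 2: PI-RADS 4.",
    "scores": [4, 4],
    "n_sig": 2,
    "status": "parsed"
  },
  {
    "name": "negative_overall_impression",
    "dialect": "structured_en",
    "text": "No suspicious focal lesions. Overall PI-RADS category: 2.",
    "scores": [2],
    "n_sig": 0,
    "status": "parsed"
  },
  {
    "name": "negative_phrase_without_scores_is_unparseable",
    "dialect": "structured_en",
    "text": "Normal examination. No focal abnormality of the prostate.",
    "scores": [],
    "n_sig": 0,
    "status": "unparseable"
  },
  {
    "name": "three_lesions_duplicates_kept",
    "dialect": "structured_en",
    "text": "Lesion 1: PI-RADS 4. Lesion 2: PI-RADS 4. Lesion 3: PI-RADS 5.",
    "scores": [4, 4, 5],
    "n_sig": 3,
    "status": "parsed"
  },
  {
    "name": "loose_any_occurrence",
    "dialect": "loose",
    "text": "Index tumour with restricted diffusion, pirads 4; second focus PI RADS: 3.",
    "scores": [4, 3],
    "n_sig": 1,
    "status": "parsed"
  },
  {
    "name": "loose_spacing_and_case",
    "dialect": "loose",
    "text": "PI - RADS   5 lesion left peripheral zone.",
    "scores": [5],
    "n_sig": 1,
    "status": "parsed"
  },
  {
    "name": "follow_up_no_score",
    "dialect": "loose",
    "text": "Follow-up study; stable appearance compared with prior examination.",
    "scores": [],
    "n_sig": 0,
    "status": "unparseable"
  }
]
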