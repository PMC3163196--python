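{
  "schema_version": "1.0",
  "metadata": {
    "name": "minimal",
    "version": "1",
    "notes": "Smallest valid model: one competency, one level-2 category covering everyone."
  },
  "skill_levels": ["basic", "advanced"],
  "region": {"population": 250000, "diagnosed_prevalence": 0.04},
  "competencies": [
    {"id": "clinical_review", "description": "routine clinical review consult", "skill_level": "basic"}
  ],
  "attributes": [
    {"id": "disease", "name": "diagnosed disease", "level": 2, "prevalence_per_10k": 10000, "provenance": "user"}
  ],
  "protocols": [
    {
      "attribute_id": "disease",
      "items": [
        {"competency_id": "clinical_review", "consults_per_year": 2, "minutes_per_consult": 20}
      ]
    }
  ]
}
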