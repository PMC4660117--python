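# Default result-classification rules. Ordered: the first matching pattern
# wins. Patterns are case-insensitive regular expressions applied to the
# free-text result of a genetic-test record. These mirror the categorical
# result strings used by the DLMP-style test template (duplicate-order
# cancellations, "... mutation ... was identified" positives, "none of the
# listed mutations were detected" negatives).
rules:
  - pattern: "cancell?ed|testing accession|NO CHARGE"
    label: CANCELLED
  - pattern: "\\b(copy|copies|mutations?|deletion|duplication|expansion)\\b.*\\bidentified\\b"
    label: POSITIVE
  - pattern: "none of the listed mutations were detected|no (known )?mutations? (was|were) detected|\\bnegative\\b"
    label: NEGATIVE
default: UNKNOWN
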