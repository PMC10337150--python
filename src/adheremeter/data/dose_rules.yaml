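# Editable rule tables for the rule-based dose-direction parser.
#
# These tables are a reconstruction of the kind of token inventory used in
# UK primary-care dose directions for inhaled asthma therapies.  They are
# deliberately shipped as data (not code) so the vocabulary can be extended
# to other conditions, formulations or languages without touching the parser.

# Number words recognised as dose quantities (digits are always accepted).
number_words:
  one: 1
  two: 2
  three: 3
  four: 4
  five: 5
  six: 6
  seven: 7
  eight: 8
  nine: 9
  ten: 10
  eleven: 11
  twelve: 12

# Words naming one administration unit.  Matching a unit word next to a
# number strengthens the quantity match but is not required.
unit_words:
  - puff
  - puffs
  - dose
  - doses
  - tablet
  - tablets
  - tab
  - tabs
  - capsule
  - capsules
  - cap
  - caps
  - inhalation
  - inhalations

# Frequency phrases -> administrations per day.  Longer phrases are matched
# before shorter ones.
frequency_phrases:
  "once a day": 1
  "once per day": 1
  "once daily": 1
  "once each day": 1
  "twice a day": 2
  "twice per day": 2
  "twice daily": 2
  "twice each day": 2
  "three times a day": 3
  "three times per day": 3
  "three times daily": 3
  "four times a day": 4
  "four times per day": 4
  "four times daily": 4
  "every morning and night": 2
  "every morning and evening": 2
  "morning and night": 2
  "morning and evening": 2
  "am and pm": 2
  "every morning": 1
  "every night": 1
  "every evening": 1
  "at night": 1
  "in the morning": 1
  "every day": 1
  "each day": 1
  "daily": 1
  "nocte": 1
  "mane": 1

# Latin abbreviations -> administrations per day (matched as whole words).
# Keys are quoted: bare "on"/"off" are YAML booleans.
latin_abbreviations:
  "od": 1
  "om": 1
  "on": 1
  "bd": 2
  "bid": 2
  "tds": 3
  "tid": 3
  "qds": 4
  "qid": 4

# Tokens flagging as-needed (symptom-driven) use.
as_needed_tokens:
  - prn
  - "as required"
  - "as needed"
  - "when needed"
  - "when required"
  - "if needed"
  - "if required"
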