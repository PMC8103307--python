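# Cue phrases for family-side assignment, living-status scoring, and
# negation detection.  All lowercase; matching is lowercase substring over
# the search region (entity text first, then the whole sentence for sides).
# The lists are supersets of the handful of examples the heuristics were
# designed around, extended with common clinical phrasings.
paternal:
  - paternal
  - "patient's father"
  - "father's"
  - father had
  - father has
  - paternal family history
  - "on the father's side"
maternal:
  - maternal
  - "patient's mother"
  - "mother's"
  - mother had
  - mother has
  - maternal family history
  - "on the mother's side"

# Living status: a not-alive cue forces score 0; otherwise a healthy cue
# gives 4; otherwise 2 (alive, health unknown).
not_alive:
  - deceased
  - passed away
  - died
  - dead
  - death
  - no longer living
  - expired
  - stillborn
healthy:
  - healthy
  - good general health
  - good health
  - in good health
  - alive and well
  - doing well
  - no health problems

# Negation pre-scope triggers (ConText style).  Multi-word triggers are
# matched as token sequences; scope runs forward to the sentence end, a
# termination conjunction, or a 6-token window, whichever comes first.
negation_triggers:
  - "no"
  - "not"
  - denies
  - denied
  - without
  - negative for
  - no history of
  - no family history of
  - not aware of
  - not significant
  - free of
negation_terminators:
  - but
  - however
  - although
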