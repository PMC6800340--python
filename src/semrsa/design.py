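"""Stimulus-design constants and epoch-length arithmetic.

The experimental design this package models is a sentence set of the form
"subject noun phrase + verb + direct-object noun", organised as sets of six
sentences: three verbs per set, each verb paired with two different
direct-object (DO) nouns.  Sixty such sets give 360 sentences.

Epoch lengths are derived from the spoken-word durations: an epoch aligned
to word onset extends forward by the mean word duration plus one standard
deviation, rounded to the nearest 10 ms.
"""

from __future__ import annotations

import math

# (mean, SD) spoken-word durations in ms for the two epoch-defining words.
VERB_DURATION_MS = (487.0, 116.0)
NOUN_DURATION_MS = (523.0, 114.0)

# Canonical design counts.
N_SETS = 60
VERBS_PER_SET = 3
NOUNS_PER_VERB = 2
N_SENTENCES = N_SETS * VERBS_PER_SET * NOUNS_PER_VERB

# Source-space sampling: epochs are analysed at 500 Hz.
SAMPLE_STEP_MS = 2.0


def epoch_length_ms(mean_ms: float, sd_ms: float, round_to: float = 10.0) -> float:
    """Epoch length covering the mean word duration plus one SD.

    The sum is rounded half-up to the nearest `round_to` milliseconds so
    that epoch boundaries fall on round sample counts.
    """
    total = mean_ms + sd_ms
    return round_to * math.floor(total / round_to + 0.5)


def verb_epoch_length_ms() -> float:
    """Length of the epoch aligned to verb onset."""
    return epoch_length_ms(*VERB_DURATION_MS)


def noun_epoch_length_ms() -> float:
    """Length of the epoch aligned to DO-noun onset."""
    return epoch_length_ms(*NOUN_DURATION_MS)
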