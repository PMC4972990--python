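"""Published summary tables of the original Filipino depression lexicon.

The raw keyword lists were never released, but the study's per-category
counts, expert content-validity ratios and source-frequency tables were.
They are recorded here as inputs: checksum tests rebuild stub lexica from the
per-category rows and verify that the toolkit's counting reproduces the
printed grand totals, and the reported CVI is recomputed from the category
CVRs.

Counts are (main keywords, derivatives, spelling variations) per category.
"""

from __future__ import annotations

# Draft lexicon, before expert validation.
# Grand totals: 1762 main, 9655 derivatives, 823,869 variations, 835,286 all.
DRAFT_COUNTS: dict[str, tuple[int, int, int]] = {
    "mood": (241, 1582, 63_340),
    "interest": (129, 1035, 107_417),
    "appetite_weight": (216, 1357, 19_032),
    "sleep": (162, 786, 187_365),
    "psychomotor_agitation": (174, 750, 12_957),
    "psychomotor_retardation": (74, 431, 16_160),
    "fatigue": (112, 424, 14_964),
    "guilt_self_esteem": (180, 1000, 30_067),
    "concentration": (165, 753, 239_291),
    "suicide": (90, 635, 58_732),
    "alcohol_substance": (63, 315, 20_875),
    "anxiety": (112, 399, 45_251),
    "histrionic": (44, 188, 8_418),
}

# Test-run lexicon, after CVR >= 0.75 retention (plus rescue).
# Grand totals: 1498 main, 8915 derivatives (column sum; the study's prose
# says 8911), 783,140 variations, 793,553 all.
VALIDATED_COUNTS: dict[str, tuple[int, int, int]] = {
    "mood": (181, 1375, 52_130),
    "interest": (113, 1011, 102_081),
    "appetite_weight": (213, 1353, 19_018),
    "sleep": (148, 743, 183_123),
    "psychomotor_agitation": (129, 544, 8_993),
    "psychomotor_retardation": (51, 366, 12_578),
    "fatigue": (103, 420, 15_080),
    "guilt_self_esteem": (173, 984, 29_837),
    "concentration": (135, 668, 229_375),
    "suicide": (86, 612, 58_355),
    "alcohol_substance": (53, 315, 20_760),
    "anxiety": (82, 359, 44_065),
    "histrionic": (31, 165, 7_745),
}

# Mean CVR of retained keywords per category, 8-expert panel.  The CVI is
# the unweighted mean of these (0.90 at 2 dp).
CATEGORY_CVRS: dict[str, float] = {
    "mood": 0.86,
    "interest": 0.93,
    "appetite_weight": 0.98,
    "sleep": 0.92,
    "psychomotor_agitation": 0.78,
    "psychomotor_retardation": 0.80,
    "fatigue": 0.89,
    "guilt_self_esteem": 0.94,
    "concentration": 0.93,
    "suicide": 0.97,
    "alcohol_substance": 0.91,
    "anxiety": 0.89,
    "histrionic": 0.92,
}

# Keyword frequency per symptom from the review of 18 depression scales
# (N=449 keywords; top row prints as 33.0% with cumulative 72.61% through
# anxiety).  Ordered by descending frequency.
SCALE_KEYWORD_FREQUENCIES: dict[str, int] = {
    "guilt_self_esteem": 148,
    "mood": 103,
    "interest": 40,
    "anxiety": 35,
    "psychomotor_agitation": 27,
    "fatigue": 23,
    "appetite_weight": 20,
    "concentration": 17,
    "sleep": 15,
    "suicide": 12,
    "psychomotor_retardation": 8,
    "histrionic": 1,
    "alcohol_substance": 0,
}

# Focus-group descriptions of depression (N=78 responses; top row prints as
# 27%).  Integer-percent table.
FOCUS_GROUP_DESCRIPTIONS: dict[str, int] = {
    "sad; lonely; unhappy": 21,
    "no focus; disturbed": 11,
    "isolation; lack of interest; low interaction": 7,
    "sleep problems": 7,
    "hopelessness; loss of meaning in life": 6,
    "fatigue; stressed": 5,
    "pessimism": 4,
    "uneasiness; instability": 4,
    "moody": 3,
    "emotional": 2,
    "eating problems": 2,
    "low self-esteem": 2,
    "suicidal": 1,
    "anxiety": 1,
    "have no emotional support": 1,
    "pretending to be happy": 1,
}

# Sample textspeak spelling variations per category: keyword -> two of its
# published variants.
SAMPLE_VARIATIONS: dict[str, tuple[str, tuple[str, str]]] = {
    "mood": ("can not stop crying", ("cant stp crying", "cnt stop cryin")),
    "interest": ("want to detach", ("wnt 2 detach", "wanna detach")),
    "sleep": ("trouble falling asleep", ("trouble fallng asleep", "trble fallin aslp")),
    "suicide": ("take my life", ("tke my life", "take my lyf")),
    "guilt_self_esteem": ("i am worthless", ("i'm wrthless", "im worthlss")),
}
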