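"""Fixed English stopword list (~150 function words) used by the tokenizer.

Removal happens before stemming, on lowercased tokens.  The list covers
determiners, pronouns, prepositions, conjunctions and high-frequency
auxiliary/light verbs; it deliberately contains no domain vocabulary.
"""

STOPWORDS = frozenset(
    """
    a about above after again against all am an and any are aren as at
    be because been before being below between both but by
    can cannot could couldn
    did didn do does doesn doing don down during
    each either
    few for from further
    had hadn has hasn have haven having he her here hers herself him himself
    his how however
    i if in into is isn it its itself
    just
    less
    may me might more most mustn my myself
    no nor not now
    of off on once only or other ought our ours ourselves out over own
    per
    same shan she should shouldn since so some such
    than that the their theirs them themselves then there these they this
    those through thus to too
    under until up upon us
    very via
    was wasn we were weren what when where which while who whom why will
    with within without won would wouldn
    yet you your yours yourself yourselves
    """.split()
)
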