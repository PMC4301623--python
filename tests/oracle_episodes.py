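"""Brute-force reference detector for the diary ALRI episode definition.

A deliberately literal, regex-based transcription of the case definition,
kept independent of the production implementation so the two can be compared
exhaustively on small diaries:

1. maximal runs of days with fever or fast/difficult breathing (regex '1+');
2. runs separated by at most 6 symptom-free days belong to one candidate
   (so accepted episodes are separated by >= 7 symptom-free days);
3. a candidate is an episode iff its first-to-last-day span is >= 2 days and
   fever and fast/difficult breathing co-occur on at least one of its days.
"""

import re


def oracle_detect(fever, fdb):
    """Return [(start, end), ...] 0-based inclusive day indices."""
    chars = "".join("1" if f or d else "0" for f, d in zip(fever, fdb))
    runs = [(m.start(), m.end() - 1) for m in re.finditer("1+", chars)]
    candidates = []
    for run in runs:
        if candidates and run[0] - candidates[-1][-1][1] - 1 <= 6:
            candidates[-1].append(run)
        else:
            candidates.append([run])
    episodes = []
    for cand in candidates:
        start, end = cand[0][0], cand[-1][1]
        if end - start + 1 < 2:
            continue
        if any(fever[i] and fdb[i] for i in range(start, end + 1)):
            episodes.append((start, end))
    return episodes
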