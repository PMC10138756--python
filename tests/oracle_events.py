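"""Brute-force splicing-event oracle for cross-checking the detector.

Deliberately written in a different style from the production code: events
are derived from base-level exonic coverage sets and explicit boundary
enumeration, with no shared helpers.  Returns events as
(type, sorted coordinate tuple) keys, the same keys `anchor_coords` yields.
"""

from itertools import combinations


def _exons(t):
    return [(e.start, e.end) for e in t.exons]


def _introns(t):
    ex = _exons(t)
    return [(ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1)]


def _exonic(t):
    bases = set()
    for s, e in _exons(t):
        bases.update(range(s, e))
    return bases


def oracle_events(transcripts):
    strand = transcripts[0].strand
    found = set()
    for t1, t2 in combinations(transcripts, 2):
        for a, b in ((t1, t2), (t2, t1)):
            cov_b = _exonic(b)
            # intron retention: the whole intron plus one flanking base on
            # each side is contiguous exonic sequence of the other isoform
            for s, e in _introns(a):
                if set(range(s - 1, e + 1)) <= cov_b:
                    found.add(("IR", tuple(sorted((s, e)))))
            # exon skipping: an intron of b spans >=1 exon of a, with a's
            # splice boundaries at both ends and no partial exon overlap
            a_ends = {x[1] for x in _exons(a)}
            a_starts = {x[0] for x in _exons(a)}
            for S, E in _introns(b):
                if S not in a_ends or E not in a_starts:
                    continue
                inside, partial = [], False
                for xs, xe in _exons(a):
                    if xs >= E or xe <= S:
                        continue
                    if S <= xs and xe <= E:
                        inside.append((xs, xe))
                    else:
                        partial = True
                if inside and not partial:
                    coords = [S, E] + [c for x in inside for c in x]
                    found.add(("ES", tuple(sorted(coords))))

        # alternative donor/acceptor sites
        for (s1, e1) in _introns(t1):
            for (s2, e2) in _introns(t2):
                if s1 == s2 and e1 != e2:
                    short = t1 if e1 < e2 else t2
                    lo, hi = min(e1, e2), max(e1, e2)
                    if set(range(lo, hi)) <= _exonic(short):
                        kind = "A3SS" if strand == "+" else "A5SS"
                        found.add((kind, tuple(sorted((s1, lo, hi)))))
                elif e1 == e2 and s1 != s2:
                    short = t1 if s1 > s2 else t2
                    lo, hi = min(s1, s2), max(s1, s2)
                    if set(range(lo, hi)) <= _exonic(short):
                        kind = "A5SS" if strand == "+" else "A3SS"
                        found.add((kind, tuple(sorted((e1, lo, hi)))))

        # mutually exclusive exons
        ex1, in1 = _exons(t1), _introns(t1)
        ex2, in2 = _exons(t2), _introns(t2)
        for i in range(1, len(ex1) - 1):
            for j in range(1, len(ex2) - 1):
                p, q = ex1[i], ex2[j]
                if not (p[1] <= q[0] or q[1] <= p[0]):
                    continue  # overlapping
                if in1[i - 1][0] != in2[j - 1][0] or in1[i][1] != in2[j][1]:
                    continue
                if _exonic(t2) & set(range(*p)) or _exonic(t1) & set(range(*q)):
                    continue
                coords = [in1[i - 1][0], in1[i][1], *p, *q]
                found.add(("MXE", tuple(sorted(coords))))
    return found
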