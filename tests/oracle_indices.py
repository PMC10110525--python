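"""Independent brute-force ETCCDI index implementations for oracle checks.

Every index is computed with explicit day-by-day loops, structurally
independent of the vectorised implementations under test.
"""

from __future__ import annotations


def oracle_index(name, tmax, tmin, precip, thr=None):
    tx = list(map(float, tmax))
    tn = list(map(float, tmin))
    p = list(map(float, precip))
    n = len(p)
    wet = [v >= 1.0 for v in p]

    def longest(flags):
        best = cur = 0
        for f in flags:
            cur = cur + 1 if f else 0
            if cur > best:
                best = cur
        return best

    def spell_total(flags, m=6):
        total = 0
        i = 0
        while i < len(flags):
            if flags[i]:
                j = i
                while j < len(flags) and flags[j]:
                    j += 1
                if j - i >= m:
                    total += j - i
                i = j
            else:
                i += 1
        return total

    if name == "RX1day":
        return max(p)
    if name == "RX5day":
        if n < 5:
            return sum(p)
        best = None
        for i in range(n - 4):
            s = sum(p[i : i + 5])
            if best is None or s > best:
                best = s
        return best
    if name == "SDII":
        nw = sum(wet)
        return sum(v for v, w in zip(p, wet) if w) / nw if nw else 0.0
    if name == "R10mm":
        return float(sum(1 for v in p if v >= 10.0))
    if name == "R20mm":
        return float(sum(1 for v in p if v >= 20.0))
    if name == "CDD":
        return float(longest([not w for w in wet]))
    if name == "CWD":
        return float(longest(wet))
    if name == "R95pTOT":
        return sum(v for v, w in zip(p, wet) if w and v > thr.r95)
    if name == "R99pTOT":
        return sum(v for v, w in zip(p, wet) if w and v > thr.r99)
    if name == "PRCPTOT":
        return sum(v for v, w in zip(p, wet) if w)
    if name == "PAVG":
        return sum(p) / n
    if name == "TXx":
        return max(tx)
    if name == "TXn":
        return min(tx)
    if name == "TNx":
        return max(tn)
    if name == "TNn":
        return min(tn)
    if name == "TX10p":
        return 100.0 * sum(1 for v in tx if v < thr.tx10) / n
    if name == "TX90p":
        return 100.0 * sum(1 for v in tx if v > thr.tx90) / n
    if name == "TN10p":
        return 100.0 * sum(1 for v in tn if v < thr.tn10) / n
    if name == "TN90p":
        return 100.0 * sum(1 for v in tn if v > thr.tn90) / n
    if name == "FD":
        return float(sum(1 for v in tn if v < 0.0))
    if name == "SU":
        return float(sum(1 for v in tx if v > 25.0))
    if name == "ID":
        return float(sum(1 for v in tx if v < 0.0))
    if name == "TR":
        return float(sum(1 for v in tn if v > 20.0))
    if name == "WSDI":
        return float(spell_total([v > thr.tx90 for v in tx]))
    if name == "CSDI":
        return float(spell_total([v < thr.tn10 for v in tn]))
    if name == "DTR":
        return sum(a - b for a, b in zip(tx, tn)) / n
    if name == "TAVG":
        return sum((a + b) / 2.0 for a, b in zip(tx, tn)) / n
    raise ValueError(name)
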