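"""Independent brute-force Gotoh dynamic program used as an alignment oracle.

Plain-Python, cell-by-cell, full three-matrix recurrence with all
gap-to-gap transitions allowed; free end gaps on the reference only.
Intentionally shares no code with nickseq.align.
"""

NEG = float("-inf")


def oracle_score(query, reference, match=2, mismatch=4, gap_open=6, gap_extend=1):
    m, n = len(query), len(reference)
    o, e = gap_open, gap_extend
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    I = [[NEG] * (n + 1) for _ in range(m + 1)]
    D = [[NEG] * (n + 1) for _ in range(m + 1)]
    for j in range(n + 1):
        M[0][j] = 0.0  # free leading reference gap
    for i in range(1, m + 1):
        for j in range(n + 1):
            best_up = max(M[i - 1][j], I[i - 1][j], D[i - 1][j])
            I[i][j] = max(I[i - 1][j] - e, best_up - o - e)
            # (reopening from I itself is included via best_up; never better)
            if j >= 1:
                qc, rc = query[i - 1], reference[j - 1]
                s = 0 if qc == "N" else (match if qc == rc else -mismatch)
                M[i][j] = max(M[i - 1][j - 1], I[i - 1][j - 1], D[i - 1][j - 1]) + s
                best_left = max(M[i][j - 1], I[i][j - 1], D[i][j - 1])
                D[i][j] = max(D[i][j - 1] - e, best_left - o - e)
    return max(max(M[m][j], I[m][j], D[m][j]) for j in range(n + 1))
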