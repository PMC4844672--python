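"""Independent brute-force oracles shared by the acceptance tests."""

BASES = "ACGT"
COMP = str.maketrans("ACGT", "TGCA")


def brute_score(pwm, seq):
    total = 0.0
    for j, ch in enumerate(seq):
        if ch not in BASES:
            return float("-inf")
        total += pwm.weights[j, BASES.index(ch)]
    return total


def brute_scan(pwm, seq, threshold):
    """Per-offset best-strand enumeration, ties to +; sorted by offset."""
    L = pwm.length
    out = []
    for off in range(len(seq) - L + 1):
        window = seq[off : off + L]
        f = brute_score(pwm, window)
        r = brute_score(pwm, window[::-1].translate(COMP))
        score, strand = (f, "+") if f >= r - 1e-9 else (r, "-")
        if score >= threshold:
            out.append((off, strand, round(score, 9)))
    return out
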