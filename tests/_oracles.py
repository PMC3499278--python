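"""Independent brute-force oracles shared by the test modules."""


def naive_scan(aa_seq, motif, max_diff):
    """Plain double-loop degenerate motif scanner."""
    k = len(motif.aa)
    out = []
    for i in range(len(aa_seq) - k + 1):
        window = aa_seq[i:i + k]
        nm = sum(1 for a, b in zip(window, motif.aa) if a != b or a in "X*")
        if nm / k < max_diff:
            out.append((i, nm))
    return out
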