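"""Independent test oracles, kept separate from the implementation path."""


def winding_number_contains(point, verts):
    """Winding-number interior test (generic position; boundary undefined)."""
    x, y = point
    wn = 0
    n = len(verts)
    for i in range(n):
        x0, y0 = verts[i]
        x1, y1 = verts[(i + 1) % n]
        if y0 <= y:
            if y1 > y and (x1 - x0) * (y - y0) - (y1 - y0) * (x - x0) > 0:
                wn += 1
        elif y1 <= y and (x1 - x0) * (y - y0) - (y1 - y0) * (x - x0) < 0:
            wn -= 1
    return wn != 0
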