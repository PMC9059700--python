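"""Shared brute-force oracle: component cleanup by explicit flood fill."""

import numpy as np


def flood_fill_components(binary, connectivity=8):
    h, w = binary.shape
    seen = np.zeros_like(binary, dtype=bool)
    nbrs = ([(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
             if (dr, dc) != (0, 0)] if connectivity == 8
            else [(-1, 0), (1, 0), (0, -1), (0, 1)])
    comps = []
    for r in range(h):
        for c in range(w):
            if binary[r, c] and not seen[r, c]:
                stack, comp = [(r, c)], []
                seen[r, c] = True
                while stack:
                    y, x = stack.pop()
                    comp.append((y, x))
                    for dr, dc in nbrs:
                        ny, nx = y + dr, x + dc
                        if (0 <= ny < h and 0 <= nx < w and binary[ny, nx]
                                and not seen[ny, nx]):
                            seen[ny, nx] = True
                            stack.append((ny, nx))
                comps.append(comp)
    return comps


def oracle_clean(raster, thr=20, min_px=100, connectivity=8):
    out = raster.copy()
    out[out < thr] = 0
    for comp in flood_fill_components(out > 0, connectivity):
        if len(comp) < min_px:
            for y, x in comp:
                out[y, x] = 0
    return out
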