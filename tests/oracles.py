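"""Independent reference implementations used only by the tests.

Each oracle is written as directly as possible (explicit loops, dense
sampling, hand arithmetic) and deliberately shares no code with the
package paths it checks.
"""

from __future__ import annotations

import numpy as np


def dense_ray_integral(dvol, geom, view: int, substeps: int = 20) -> np.ndarray:
    """Line integrals by dense midpoint sampling at 1/substeps-voxel steps,
    treating the volume as piecewise constant over voxels (nearest-voxel
    lookup).  Reference for the exact-path-length ray tracer."""
    src = geom.source_position(view)
    rows, cols = geom.pixel_centers_mm()
    h = dvol.voxel_size_mm
    step = h / substeps
    o = dvol.origin_mm - h / 2          # voxel (0,0,0) face
    shape = np.array(dvol.values.shape)
    out = np.zeros(geom.detector_shape)
    for r, ym in enumerate(rows):
        for c, xm in enumerate(cols):
            p1 = np.array([xm, ym, 0.0])
            d = p1 - src
            L = np.linalg.norm(d)
            tmin, tmax = 0.0, 1.0
            ok = True
            for ax in range(3):
                lo, hi = o[ax], o[ax] + shape[ax] * h
                if d[ax] == 0:
                    if not lo <= src[ax] <= hi:
                        ok = False
                        break
                else:
                    t1, t2 = (lo - src[ax]) / d[ax], (hi - src[ax]) / d[ax]
                    tmin = max(tmin, min(t1, t2))
                    tmax = min(tmax, max(t1, t2))
            if not ok or tmin >= tmax:
                continue
            n = int(np.ceil((tmax - tmin) * L / step))
            ts = tmin + (np.arange(n) + 0.5) * (tmax - tmin) / n
            pts = src + ts[:, None] * d
            idx = np.floor((pts - o) / h).astype(int)
            inside = np.all((idx >= 0) & (idx < shape), axis=1)
            out[r, c] = dvol.values[idx[inside, 0], idx[inside, 1],
                                    idx[inside, 2]].sum() * (tmax - tmin) * L / n
    return out


def phantom_region_membership(spec, ribs) -> np.ndarray:
    """Brute-force voxel-center membership test reproducing the phantom's
    painting order with independently written predicates.  ``ribs`` is the
    list of (height, major radius, tube radius) the generator drew.
    Returns the region id grid (0 bg, 1 body, 2 lung, 3 bone, 4 nodule)."""
    nx, ny, nz = spec.grid_shape
    h = spec.voxel_size_mm
    region = np.zeros((nx, ny, nz), dtype=np.uint8)
    for i in range(nx):
        x = (i - (nx - 1) / 2) * h
        for j in range(ny):
            y = (j - (ny - 1) / 2) * h
            for k in range(nz):
                z = (k - (nz - 1) / 2) * h
                rid = 0
                if spec.body_halfaxes_mm is not None:
                    A = spec.body_halfaxes_mm
                    if (x / A[0])**2 + (y / A[1])**2 + (z / A[2])**2 < 1:
                        rid = 1
                        a = spec.lung_halfaxes_mm
                        if a is not None:
                            for off in spec.lung_offsets_mm:
                                if (((x - off[0]) / a[0])**2 + ((y - off[1]) / a[1])**2
                                        + ((z - off[2]) / a[2])**2) < 1:
                                    rid = 2
                        if spec.spine_radius_mm > 0:
                            z_sp = -0.5 * A[2]
                            if (x * x + (z - z_sp)**2 < spec.spine_radius_mm**2
                                    and abs(y) < 0.8 * A[1]):
                                rid = 3
                        for (y0, major, tube) in ribs:
                            if (np.sqrt(x * x + z * z) - major)**2 + (y - y0)**2 < tube**2:
                                rid = 3
                for (c, rad) in spec.nodules:
                    if (x - c[0])**2 + (y - c[1])**2 + (z - c[2])**2 < rad**2:
                        rid = 4
                region[i, j, k] = rid
    return region


def loop_gather_patch(images: np.ndarray, cols, strip_width: int) -> np.ndarray:
    """Explicit-loop strip gather with zero padding; reference for
    extract_patch."""
    n_views, n_rows, n_cols = images.shape
    out = np.zeros((n_views, n_rows, strip_width))
    for v in range(n_views):
        for r in range(n_rows):
            for w, c in enumerate(cols):
                if 0 <= c < n_cols:
                    out[v, r, w] = images[v, r, c]
    return out


def hand_confusion(true_labels, pred_labels) -> np.ndarray:
    """Flat-loop 3x3 confusion counts."""
    counts = np.zeros((3, 3), dtype=np.int64)
    for t, p in zip(np.ravel(true_labels), np.ravel(pred_labels)):
        counts[int(t), int(p)] += 1
    return counts


def hand_gdl(probs, onehot, eps=1e-6) -> float:
    """Direct arithmetic evaluation of generalized Dice over flat pixels."""
    p = np.reshape(probs, (-1, 3))
    g = np.reshape(onehot, (-1, 3))
    num = den = 0.0
    for c in range(3):
        w = 1.0 / (g[:, c].sum() + eps) ** 2
        num += w * float((p[:, c] * g[:, c]).sum())
        den += w * float((p[:, c] + g[:, c]).sum())
    return 1.0 - 2.0 * num / (den + eps)


def hand_ce(probs, onehot) -> float:
    p = np.clip(np.reshape(probs, (-1, 3)), 1e-7, 1.0)
    g = np.reshape(onehot, (-1, 3))
    total = 0.0
    for i in range(p.shape[0]):
        for c in range(3):
            total -= g[i, c] * np.log(p[i, c])
    return total / p.shape[0]


def layerwise_param_count(cfg) -> int:
    """Closed-form per-layer arithmetic audit of the model parameter count,
    written against the architecture contract (kernel volume x in x out
    + biases), independent of both the model and its config audit."""
    v, r, w = cfg.input_shape
    total, in_ch = 0, 1
    enc_shapes = []
    for out_ch, (sv, sr, sw) in zip(cfg.encoder_channels, cfg.encoder_strides):
        total += 3 * 3 * 3 * in_ch * out_ch + out_ch
        v, r, w = -(-v // sv), -(-r // sr), -(-w // sw)
        enc_shapes.append((out_ch, v, r, w))
        in_ch = out_ch
    kd = len(cfg.decoder_channels)
    seed_rows = cfg.output_shape[0] // 2**kd
    seed_depth = cfg.output_shape[1] // 2**kd
    total += (in_ch * v * w) * (cfg.seed_channels * seed_depth) \
        + cfg.seed_channels * seed_depth
    in_ch = cfg.seed_channels
    for j, out_ch in enumerate(cfg.decoder_channels):
        total += 3 * 3 * in_ch * out_ch + out_ch
        rows_j = seed_rows * 2 ** (j + 1)
        src = None
        for (c, vv, rr, ww) in enc_shapes:
            if rr == rows_j:
                src = (c, vv, ww)
        if src is not None:
            total += src[0] * src[1] * src[2] * out_ch + out_ch
        in_ch = out_ch
    total += in_ch * 3 + 3
    return total
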