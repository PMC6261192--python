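"""Independent brute-force oracles used by the tests.

Everything here is written as plain scalar Python loops, directly from the
textbook definitions, deliberately sharing no code with the package's
vectorized implementations.
"""

import math


def binning_oracle(values, n_bins, lo, hi):
    """1-based bin per value, clamping out-of-range values into edge bins."""
    width = (hi - lo) / n_bins
    out = []
    for v in values:
        b = int(math.floor((v - lo) / width)) + 1
        out.append(min(max(b, 1), n_bins))
    return out


def glcm_oracle(bins, mask, direction, n_levels):
    """Symmetric normalized co-occurrence probabilities by pair enumeration."""
    nx, ny, nz = mask.shape
    dx, dy, dz = direction
    counts = [[0.0] * n_levels for _ in range(n_levels)]
    total = 0
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                X, Y, Z = x + dx, y + dy, z + dz
                if not (0 <= X < nx and 0 <= Y < ny and 0 <= Z < nz):
                    continue
                if not mask[X, Y, Z]:
                    continue
                i, j = bins[x, y, z] - 1, bins[X, Y, Z] - 1
                counts[i][j] += 1
                counts[j][i] += 1
                total += 2
    if total == 0:
        return None
    return [[c / total for c in row] for row in counts]


def glcm_features_oracle(p):
    """The 21 co-occurrence features, scalar loops, log base 2."""
    N = len(p)

    def log2(v):
        return math.log(v, 2)

    px = [sum(p[i][j] for j in range(N)) for i in range(N)]
    py = [sum(p[i][j] for i in range(N)) for j in range(N)]
    mu = sum((i + 1) * px[i] for i in range(N))
    var = sum((i + 1 - mu) ** 2 * px[i] for i in range(N))

    acorr = sum((i + 1) * (j + 1) * p[i][j] for i in range(N) for j in range(N))
    prom = shade = tend = 0.0
    contrast = dissim = 0.0
    energy = entropy = 0.0
    homog = homog2 = idmn = idm2n = invvar = 0.0
    maxp = 0.0
    for i in range(N):
        for j in range(N):
            q = p[i][j]
            s = (i + 1) + (j + 1) - 2 * mu
            d = abs(i - j)
            prom += s**4 * q
            shade += s**3 * q
            tend += s**2 * q
            contrast += d**2 * q
            dissim += d * q
            energy += q * q
            if q > 0:
                entropy -= q * log2(q)
            homog += q / (1 + d)
            homog2 += q / (1 + d * d)
            idmn += q / (1 + d / N)
            idm2n += q / (1 + d * d / (N * N))
            if d > 0:
                invvar += q / (d * d)
            maxp = max(maxp, q)
    corr = (acorr - mu * mu) / var if var > 0 else float("nan")

    p_sum = [0.0] * (2 * N + 1)
    p_diff = [0.0] * N
    for i in range(N):
        for j in range(N):
            p_sum[(i + 1) + (j + 1)] += p[i][j]
            p_diff[abs(i - j)] += p[i][j]
    sum_avg = sum(k * p_sum[k] for k in range(2, 2 * N + 1))
    sum_ent = -sum(q * log2(q) for q in p_sum if q > 0)
    diff_ent = -sum(q * log2(q) for q in p_diff if q > 0)

    hxy = entropy
    hx = -sum(q * log2(q) for q in px if q > 0)
    hxy1 = hxy2 = 0.0
    for i in range(N):
        for j in range(N):
            pq = px[i] * py[j]
            if pq > 0:
                hxy2 -= pq * log2(pq)
                if p[i][j] > 0:
                    hxy1 -= p[i][j] * log2(pq)
    imoc1 = (hxy - hxy1) / hx if hx > 0 else float("nan")
    imoc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))

    return {
        "glcm_autocorrelation": acorr,
        "glcm_cluster_prominence": prom,
        "glcm_cluster_shade": shade,
        "glcm_cluster_tendency": tend,
        "glcm_contrast": contrast,
        "glcm_correlation": corr,
        "glcm_difference_entropy": diff_ent,
        "glcm_dissimilarity": dissim,
        "glcm_energy": energy,
        "glcm_entropy": hxy,
        "glcm_homogeneity": homog,
        "glcm_homogeneity_2": homog2,
        "glcm_imoc1": imoc1,
        "glcm_imoc2": imoc2,
        "glcm_inverse_difference_moment": idmn,
        "glcm_inverse_difference_moment_2": idm2n,
        "glcm_inertia": contrast,
        "glcm_inverse_variance": invvar,
        "glcm_max_probability": maxp,
        "glcm_sum_average": sum_avg,
        "glcm_sum_entropy": sum_ent,
    }


def glrlm_oracle(bins, mask, direction, n_levels):
    """Run counts by walking every line start; returns (matrix, n_voxels)."""
    nx, ny, nz = mask.shape
    dx, dy, dz = direction

    def inside(x, y, z):
        return 0 <= x < nx and 0 <= y < ny and 0 <= z < nz and mask[x, y, z]

    runs = []
    n_vox = 0
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                n_vox += 1
                # a run starts where the predecessor along the direction is
                # outside the mask or has a different gray level
                px_, py_, pz_ = x - dx, y - dy, z - dz
                if inside(px_, py_, pz_) and bins[px_, py_, pz_] == bins[x, y, z]:
                    continue
                g = bins[x, y, z]
                length = 0
                cx, cy, cz = x, y, z
                while inside(cx, cy, cz) and bins[cx, cy, cz] == g:
                    length += 1
                    cx, cy, cz = cx + dx, cy + dy, cz + dz
                runs.append((g, length))
    if not runs:
        return None, 0
    max_len = max(l for _, l in runs)
    mat = [[0.0] * max_len for _ in range(n_levels)]
    for g, l in runs:
        mat[g - 1][l - 1] += 1
    return mat, n_vox


def glrlm_features_oracle(mat, n_vox):
    """The 11 run-length features, scalar loops."""
    N = len(mat)
    R = len(mat[0])
    nr = sum(sum(row) for row in mat)
    sre = lre = gln = rln = lgle = hgle = 0.0
    srlgle = srhgle = lrlgle = lrhgle = 0.0
    for i in range(N):
        gi = 0.0
        for j in range(R):
            r = mat[i][j]
            gi += r
            i2 = (i + 1) ** 2
            j2 = (j + 1) ** 2
            sre += r / j2
            lre += r * j2
            lgle += r / i2
            hgle += r * i2
            srlgle += r / (i2 * j2)
            srhgle += r * i2 / j2
            lrlgle += r * j2 / i2
            lrhgle += r * i2 * j2
        gln += gi * gi
    for j in range(R):
        rj = sum(mat[i][j] for i in range(N))
        rln += rj * rj
    return {
        "glrlm_gray_level_nonuniformity": gln / nr,
        "glrlm_high_gray_level_emphasis": hgle / nr,
        "glrlm_long_run_emphasis": lre / nr,
        "glrlm_long_run_high_gray_level_emphasis": lrhgle / nr,
        "glrlm_long_run_low_gray_level_emphasis": lrlgle / nr,
        "glrlm_low_gray_level_emphasis": lgle / nr,
        "glrlm_run_length_nonuniformity": rln / nr,
        "glrlm_run_percentage": nr / n_vox,
        "glrlm_short_run_emphasis": sre / nr,
        "glrlm_short_run_high_gray_level_emphasis": srhgle / nr,
        "glrlm_short_run_low_gray_level_emphasis": srlgle / nr,
    }


def icc_anova_oracle(a, b):
    """Two-way consistency ICC from explicit ANOVA sums of squares."""
    n = len(a)
    k = 2
    allv = list(a) + list(b)
    grand = sum(allv) / (n * k)
    row_means = [(a[i] + b[i]) / 2 for i in range(n)]
    col_means = [sum(a) / n, sum(b) / n]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_cols = n * sum((m - grand) ** 2 for m in col_means)
    ss_tot = sum((v - grand) ** 2 for v in allv)
    ss_err = ss_tot - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)


def moment_oracle(values):
    """Population skewness and non-excess kurtosis by direct summation."""
    n = len(values)
    m = sum(values) / n
    m2 = sum((v - m) ** 2 for v in values) / n
    m3 = sum((v - m) ** 3 for v in values) / n
    m4 = sum((v - m) ** 4 for v in values) / n
    return m3 / m2**1.5, m4 / m2**2
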