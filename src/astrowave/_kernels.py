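"""Inner time-stepping kernels for the coupled cell/field system.

The forward-Euler / Euler–Maruyama update of all cells plus the FTCS field
update is implemented twice with identical arithmetic: a numba-compiled
version used when numba is importable, and a vectorized numpy fallback.
Both advance the state arrays in place over a chunk of steps, consuming a
pre-drawn array of standard-normal increments so that trajectories are
reproducible and independent of the backend.

Per step (all cells, then the field):
  1. sample the local ATP concentration at each cell (bilinear weights)
  2. evaluate fluxes and advance C, h, C_ER by forward Euler; advance IP3
     by Euler–Maruyama (drift·dt + σ·√dt·N(0,1))
  3. clamp C, C_ER, I at 0 and h to [0, 1]
  4. deposit ATP released at the pre-step calcium onto the four stencil
     nodes (concentration increment j_ATP·dt/spacing² per grid cell)
  5. FTCS diffusion–decay update with zero-flux boundaries; clamp at 0
"""

from __future__ import annotations

import numpy as np

from .params import ModelParams

# packed parameter-vector layout shared by both kernels
_P_FIELDS = (
    "beta", "k_l_ext", "C_ext", "j_ip3r_max", "k_C", "k_I", "k_off", "k_on",
    "j_serca_max", "k_serca2", "R_vol", "k_l_er", "k1p", "k2p", "V1", "V2",
    "k_deg", "r_h", "k_atp", "kd_ka", "delta", "D", "alpha", "k_rel",
    "C_min", "j_atp_max", "sigma",
)


def pack_kernel_params(p: ModelParams) -> np.ndarray:
    return np.array(
        [
            p.beta, p.k_l_ext, p.C_ext, p.j_ip3r_max, p.k_C, p.k_I, p.k_off,
            p.k_on, p.j_serca_max, p.k_serca ** 2, p.R_vol, p.k_l_er,
            p.k1 ** 1.7, p.k2 ** 4.4, p.V1, p.V2, p.k_deg, p.r_h, p.k_atp,
            p.kd_over_ka, p.delta, p.D, p.alpha, p.k_rel, p.C_min,
            p.j_atp_max, p.sigma,
        ],
        dtype=np.float64,
    )


def _advance_chunk_py(C, h, CER, I, A, idx, w, noise, dt, spacing, G_glu, pv):
    """Numpy reference implementation (same arithmetic as the numba path)."""
    (beta, k_l_ext, C_ext, j_ip3r_max, k_C, k_I, k_off, k_on, j_serca_max,
     k_serca2, R_vol, k_l_er, k1p, k2p, V1, V2, k_deg, r_h, k_atp, kd_ka,
     delta, D, alpha, k_rel, C_min, j_atp_max, sigma) = pv
    nsteps = noise.shape[0]
    sqrt_dt = np.sqrt(dt)
    dep_scale = dt / spacing ** 2
    flat = A.ravel()
    for s in range(nsteps):
        A_loc = (flat[idx] * w).sum(axis=1)
        rho = A_loc / (k_atp + A_loc)
        G_atp = (rho + delta) / (kd_ka + delta + rho)
        gate = (C / (C + k_C)) * (I / (I + k_I)) * h
        drive = 1.0 - C / CER
        j_ip3r = j_ip3r_max * gate ** 3 * drive
        c2 = C * C
        j_serca = j_serca_max * c2 / (c2 + k_serca2)
        j_ler = k_l_er * drive
        c17 = C ** 1.7
        c44 = C ** 4.4
        j_pca = V1 * c17 / (k1p + c17) + V2 * c44 / (k2p + c44)
        j_lext = k_l_ext * (1.0 - C / C_ext)
        j_atp = np.where(C > C_min, j_atp_max * (C - C_min) / (k_rel + C), 0.0)
        C_new = C + dt * beta * (j_ip3r - j_serca + j_ler - j_pca + j_lext)
        h_new = h + dt * k_off * (k_on - (C + k_on) * h)
        CER_new = CER + dt * R_vol * (j_serca - j_ip3r - j_ler)
        I_new = I + dt * (r_h * (G_atp + G_glu) - k_deg * I) \
            + sigma * sqrt_dt * noise[s]
        np.maximum(C_new, 0.0, out=C)
        np.clip(h_new, 0.0, 1.0, out=h)
        np.maximum(CER_new, 0.0, out=CER)
        np.maximum(I_new, 0.0, out=I)
        np.add.at(flat, idx.ravel(), (w * (j_atp * dep_scale)[:, None]).ravel())
        padded = np.pad(A, 1, mode="edge")
        lap = (
            padded[:-2, 1:-1] + padded[2:, 1:-1]
            + padded[1:-1, :-2] + padded[1:-1, 2:] - 4.0 * A
        ) / spacing ** 2
        A += dt * (D * lap - alpha * A)
        np.maximum(A, 0.0, out=A)


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    @njit(cache=True)
    def _advance_chunk_nb(C, h, CER, I, A, idx, w, noise, dt, spacing,
                          G_glu, pv):
        beta = pv[0]; k_l_ext = pv[1]; C_ext = pv[2]; j_ip3r_max = pv[3]
        k_C = pv[4]; k_I = pv[5]; k_off = pv[6]; k_on = pv[7]
        j_serca_max = pv[8]; k_serca2 = pv[9]; R_vol = pv[10]; k_l_er = pv[11]
        k1p = pv[12]; k2p = pv[13]; V1 = pv[14]; V2 = pv[15]; k_deg = pv[16]
        r_h = pv[17]; k_atp = pv[18]; kd_ka = pv[19]; delta = pv[20]
        D = pv[21]; alpha = pv[22]; k_rel = pv[23]; C_min = pv[24]
        j_atp_max = pv[25]; sigma = pv[26]

        nsteps = noise.shape[0]
        N = C.shape[0]
        ny, nx = A.shape
        flat = A.ravel()
        lapbuf = np.empty((ny, nx))
        sqrt_dt = np.sqrt(dt)
        dep_scale = dt / spacing ** 2
        inv_h2 = 1.0 / (spacing * spacing)
        for s in range(nsteps):
            for i in range(N):
                A_loc = (flat[idx[i, 0]] * w[i, 0] + flat[idx[i, 1]] * w[i, 1]
                         + flat[idx[i, 2]] * w[i, 2] + flat[idx[i, 3]] * w[i, 3])
                rho = A_loc / (k_atp + A_loc)
                G_atp = (rho + delta) / (kd_ka + delta + rho)
                Ci = C[i]; hi = h[i]; CERi = CER[i]; Ii = I[i]
                gate = (Ci / (Ci + k_C)) * (Ii / (Ii + k_I)) * hi
                drive = 1.0 - Ci / CERi
                j_ip3r = j_ip3r_max * gate ** 3 * drive
                c2 = Ci * Ci
                j_serca = j_serca_max * c2 / (c2 + k_serca2)
                j_ler = k_l_er * drive
                c17 = Ci ** 1.7
                c44 = Ci ** 4.4
                j_pca = V1 * c17 / (k1p + c17) + V2 * c44 / (k2p + c44)
                j_lext = k_l_ext * (1.0 - Ci / C_ext)
                if Ci > C_min:
                    j_atp = j_atp_max * (Ci - C_min) / (k_rel + Ci)
                else:
                    j_atp = 0.0
                Cn = Ci + dt * beta * (j_ip3r - j_serca + j_ler - j_pca + j_lext)
                hn = hi + dt * k_off * (k_on - (Ci + k_on) * hi)
                CERn = CERi + dt * R_vol * (j_serca - j_ip3r - j_ler)
                In = Ii + dt * (r_h * (G_atp + G_glu) - k_deg * Ii) \
                    + sigma * sqrt_dt * noise[s, i]
                C[i] = Cn if Cn > 0.0 else 0.0
                h[i] = 0.0 if hn < 0.0 else (1.0 if hn > 1.0 else hn)
                CER[i] = CERn if CERn > 0.0 else 0.0
                I[i] = In if In > 0.0 else 0.0
                amt = j_atp * dep_scale
                flat[idx[i, 0]] += w[i, 0] * amt
                flat[idx[i, 1]] += w[i, 1] * amt
                flat[idx[i, 2]] += w[i, 2] * amt
                flat[idx[i, 3]] += w[i, 3] * amt
            for jy in range(ny):
                jm = jy - 1 if jy > 0 else 0
                jp = jy + 1 if jy < ny - 1 else ny - 1
                for jx in range(nx):
                    im = jx - 1 if jx > 0 else 0
                    ip = jx + 1 if jx < nx - 1 else nx - 1
                    lapbuf[jy, jx] = (
                        A[jm, jx] + A[jp, jx] + A[jy, im] + A[jy, ip]
                        - 4.0 * A[jy, jx]
                    ) * inv_h2
            for jy in range(ny):
                for jx in range(nx):
                    An = A[jy, jx] + dt * (D * lapbuf[jy, jx]
                                           - alpha * A[jy, jx])
                    A[jy, jx] = An if An > 0.0 else 0.0

    advance_chunk = _advance_chunk_nb
    BACKEND = "numba"
except Exception:  # pragma: no cover
    advance_chunk = _advance_chunk_py
    BACKEND = "numpy"
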