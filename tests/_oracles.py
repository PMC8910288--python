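"""Independent reference computations used to cross-check the package.

The wave-equation oracle solves the one-dimensional Helmholtz problem for a
sharp-interface slab profile directly as a linear boundary-value system
(continuity of the wavefunction and its derivative at every interface),
which shares no code or algorithm with the package's interface recursion.
"""

from __future__ import annotations

import numpy as np


def wave_equation_reflectivity(q, slds, thickness):
    """|r|^2 for a sharp-interface stack by direct linear-system solution.

    ``slds`` in 1e-6 A^-2 including fronting and backing; ``thickness`` for
    the interior layers only.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    slds = np.asarray(slds, dtype=float) * 1e-6
    thickness = np.asarray(thickness, dtype=float)
    m = len(thickness)
    z = np.concatenate([[0.0], np.cumsum(thickness)])  # interface positions
    out = np.empty_like(q)
    for iq, qq in enumerate(q):
        kz0 = qq / 2.0
        k = np.sqrt(
            np.asarray(kz0**2 - 4.0 * np.pi * (slds - slds[0]), dtype=complex)
        )
        # unknowns: r, A_1, B_1, ..., A_m, B_m, t
        n_unk = 2 * m + 2
        A = np.zeros((n_unk, n_unk), dtype=complex)
        b = np.zeros(n_unk, dtype=complex)

        def wave_coeff_cols(j):
            # column indices of (A_j, B_j) for medium j (1..m); medium 0 is
            # fronting (unknown r at col 0), medium m+1 backing (t at col -1)
            return 1 + 2 * (j - 1), 2 + 2 * (j - 1)

        row = 0
        for i in range(m + 1):  # interface i at z[i], between media i and i+1
            zi = z[i]
            # left side
            if i == 0:
                l_val = [(0, np.exp(-1j * k[0] * zi))]
                l_der = [(0, -1j * k[0] * np.exp(-1j * k[0] * zi))]
                const_val = np.exp(1j * k[0] * zi)
                const_der = 1j * k[0] * np.exp(1j * k[0] * zi)
            else:
                ca, cb = wave_coeff_cols(i)
                l_val = [
                    (ca, np.exp(1j * k[i] * zi)),
                    (cb, np.exp(-1j * k[i] * zi)),
                ]
                l_der = [
                    (ca, 1j * k[i] * np.exp(1j * k[i] * zi)),
                    (cb, -1j * k[i] * np.exp(-1j * k[i] * zi)),
                ]
                const_val = const_der = 0.0
            # right side
            if i == m:
                r_val = [(n_unk - 1, np.exp(1j * k[m + 1] * zi))]
                r_der = [(n_unk - 1, 1j * k[m + 1] * np.exp(1j * k[m + 1] * zi))]
            else:
                ca, cb = wave_coeff_cols(i + 1)
                r_val = [
                    (ca, np.exp(1j * k[i + 1] * zi)),
                    (cb, np.exp(-1j * k[i + 1] * zi)),
                ]
                r_der = [
                    (ca, 1j * k[i + 1] * np.exp(1j * k[i + 1] * zi)),
                    (cb, -1j * k[i + 1] * np.exp(-1j * k[i + 1] * zi)),
                ]
            for col, val in l_val:
                A[row, col] += val
            for col, val in r_val:
                A[row, col] -= val
            b[row] = -const_val
            row += 1
            for col, val in l_der:
                A[row, col] += val
            for col, val in r_der:
                A[row, col] -= val
            b[row] = -const_der
            row += 1
        sol = np.linalg.solve(A, b)
        out[iq] = abs(sol[0]) ** 2
    return out


def fresnel_reflectivity(q, rho_front, rho_back):
    """Closed-form Fresnel |r|^2 of a single sharp interface (SLDs 1e-6 A^-2)."""
    q = np.asarray(q, dtype=float)
    kz = q / 2.0
    k1 = np.sqrt(
        np.asarray(kz**2 - 4.0 * np.pi * (rho_back - rho_front) * 1e-6, dtype=complex)
    )
    r = (kz - k1) / (kz + k1)
    return np.abs(r) ** 2
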