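#!/usr/bin/env python
"""Provenance of the ideal-helix backbone placement constants.

Builds a poly-backbone alpha-helix from standard internal coordinates
(phi = -57, psi = -47, omega = 180; standard bond lengths and angles),
fits the helix axis, and prints the cylindrical coordinates of N, C and
O relative to the CA trace. The printed (radius, phase offset, z offset)
triples are the ``_BACKBONE_OFFSETS`` frozen in ``helix8.synthetic``;
rerun this script to re-derive them.
"""
import numpy as np

# standard backbone geometry (lengths in A, angles in degrees)
B_N_CA, B_CA_C, B_C_N, B_C_O = 1.458, 1.525, 1.329, 1.231
A_N_CA_C, A_CA_C_N, A_C_N_CA = 111.2, 116.2, 121.7
A_CA_C_O = 120.8
PHI, PSI, OMEGA = -57.0, -47.0, 180.0


def place(a, b, c, bond, angle, dihedral):
    """Natural-extension placement of atom d on chain a-b-c."""
    angle = np.radians(angle)
    dihedral = np.radians(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-bond * np.cos(angle),
                   bond * np.sin(angle) * np.cos(dihedral),
                   bond * np.sin(angle) * np.sin(dihedral)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def build(n_res):
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([B_N_CA, 0.0, 0.0])]
    ang = np.radians(180 - A_N_CA_C)
    C = [CA[0] + np.array([B_CA_C * np.cos(ang), B_CA_C * np.sin(ang), 0.0])]
    for _ in range(1, n_res):
        Ni = place(N[-1], CA[-1], C[-1], B_C_N, A_CA_C_N, PSI)
        CAi = place(CA[-1], C[-1], Ni, B_N_CA, A_C_N_CA, OMEGA)
        Ci = place(C[-1], Ni, CAi, B_CA_C, A_N_CA_C, PHI)
        N.append(Ni)
        CA.append(CAi)
        C.append(Ci)
    # carbonyl O in the peptide plane, anti to the next N
    O = [place(N[i + 1], CA[i], C[i], B_C_O, A_CA_C_O, 180.0) for i in range(n_res - 1)]
    return map(np.array, (N, CA, C, O))


def cylindrical(P, axis, origin, ref_radial):
    z = (P - origin) @ axis
    radial = (P - origin) - np.outer(z, axis)
    r = np.linalg.norm(radial, axis=1)
    e1 = ref_radial / np.linalg.norm(ref_radial)
    e2 = np.cross(axis, e1)
    phi = np.degrees(np.arctan2(radial @ e2, radial @ e1))
    return r, phi, z


def main():
    n_res = 24
    N, CA, C, O = build(n_res)
    sl = slice(4, 20)  # discard 4 residues per end (end effects)
    d = CA[sl][1:] - CA[sl][:-1]
    axis = d.mean(axis=0)
    axis /= np.linalg.norm(axis)
    origin = CA[sl].mean(axis=0)
    z0 = (CA[sl][0] - origin) @ axis
    ref_radial = (CA[sl][0] - origin) - z0 * axis

    rCA, phiCA, zCA = cylindrical(CA[sl], axis, origin, ref_radial)
    twist = np.diff(np.unwrap(np.radians(phiCA))).mean() * 180 / np.pi
    print(f"CA: radius {rCA.mean():.4f} A, rise/res {np.diff(zCA).mean():.4f} A, "
          f"twist/res {twist:.2f} deg")
    for name, P in (("N", N[sl]), ("C", C[sl]), ("O", O[4:20])):
        r, phi, z = cylindrical(P, axis, origin, ref_radial)
        dphi = (phi - phiCA + 180) % 360 - 180
        print(f"{name}: radius {r.mean():.4f} A, phase offset {dphi.mean():.2f} deg, "
              f"z offset {(z - zCA).mean():.4f} A")
    dON = [np.linalg.norm(O[i] - N[i + 4]) for i in range(6, 16)]
    print(f"O(i)..N(i+4) distance: {np.mean(dON):.3f} A")


if __name__ == "__main__":
    main()
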