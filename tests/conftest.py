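"""Shared fixtures: synthetic couples and tiny hand-built PDB texts."""

from __future__ import annotations

import pytest

from fabcompare import (
    SyntheticSpec,
    generate_couple,
    spec_b1,
    spec_b2,
    spec_b3,
)


def pdb_atom_line(serial, name, resname, chain, resseq, xyz, occ=1.0,
                  altloc=" ", icode=" ") -> str:
    """One fixed-column ATOM record (independent of the package's writer)."""
    return (
        f"ATOM  {serial:5d} {name:^4s}{altloc}{resname:>3s} {chain}"
        f"{resseq:4d}{icode}   {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{occ:6.2f}{0.0:6.2f}          {name[0]:>2s}"
    )


def make_pdb_text(residues, chain="A", header_resolution=None,
                  start_serial=1) -> str:
    """Build PDB text from [(resname, resseq, icode, {atom: xyz})] entries."""
    lines = []
    if header_resolution is not None:
        lines.append(
            f"REMARK   2 RESOLUTION.    {header_resolution:4.2f} ANGSTROMS."
        )
    serial = start_serial
    for resname, resseq, icode, atoms in residues:
        for name, xyz in atoms.items():
            lines.append(pdb_atom_line(serial, name, resname, chain, resseq,
                                       xyz, icode=icode))
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def straight_backbone(n, spacing=3.8, origin=(0.0, 0.0, 0.0)):
    """N/CA/C/O atom dicts for an ideal straight chain along x."""
    out = []
    for i in range(n):
        x = origin[0] + i * spacing
        out.append({
            "N": (x - 1.2, origin[1], origin[2]),
            "CA": (x, origin[1], origin[2]),
            "C": (x + 1.2, origin[1], origin[2]),
            "O": (x + 1.2, origin[1] + 1.2, origin[2]),
        })
    return out


@pytest.fixture(scope="session")
def couple_b1():
    return generate_couple(spec_b1(seed=11))


@pytest.fixture(scope="session")
def couple_b2():
    return generate_couple(spec_b2(seed=12))


@pytest.fixture(scope="session")
def couple_b3():
    return generate_couple(spec_b3(seed=13))


@pytest.fixture(scope="session")
def clean_hinge_couple():
    """Hinge-only couple, no loops, no noise: sharpest recovery checks."""
    return generate_couple(SyntheticSpec(
        hinge_angle_heavy=-20.0, hinge_angle_light=20.0, noise_sigma=0.0,
        seed=7,
    ))


@pytest.fixture(scope="session")
def identical_couple():
    """No deformation, no noise: bound is bit-identical to free."""
    return generate_couple(SyntheticSpec(noise_sigma=0.0, seed=5))
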