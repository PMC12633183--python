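import numpy as np
import pytest

from synthscreen.capselect import CapSite, DockedPose
from synthscreen.fixtures import LibrarySpec, PocketSpec, make_pocket, make_toy_library


@pytest.fixture(scope="session")
def mixed_library():
    """Small library with 2-component, 3-component and bridge chemistry."""
    return make_toy_library(
        LibrarySpec(
            two_component=((3, 4),),
            three_component=((2, 2, 2),),
            bridge=((2, 2, 3),),
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def deadend_pocket():
    pocket, meta = make_pocket(
        PocketSpec(kind="deadend", radius=4.0, length=16.0, spacing=1.0, layers=3)
    )
    return pocket, meta


def two_atom_pose(anchor, cap, cap_type="methyl", ref="pose", extra_caps=()):
    """Minimal pose: anchor/cap carbon pairs, one pair per cap site.

    ``extra_caps`` entries are ``(label, anchor_xyz, cap_xyz, cap_type)``.
    """
    coords = [np.asarray(anchor, dtype=float), np.asarray(cap, dtype=float)]
    sites = {
        "1": CapSite(
            label="1", cap_type=cap_type, cap_atom=1, anchor_atom=0, members=(1,)
        )
    }
    for label, anchor_xyz, cap_xyz, ctype in extra_caps:
        a_idx = len(coords)
        coords.append(np.asarray(anchor_xyz, dtype=float))
        c_idx = len(coords)
        coords.append(np.asarray(cap_xyz, dtype=float))
        sites[label] = CapSite(
            label=label,
            cap_type=ctype,
            cap_atom=c_idx,
            anchor_atom=a_idx,
            members=(c_idx,),
        )
    return DockedPose(
        fragment_ref=ref,
        elements=("C",) * len(coords),
        coords=np.array(coords),
        dock_score=-10.0,
        caps=sites,
    )


def exhaustive_products(lib):
    """Canonical SMILES set from full recursive enumeration of every MEL."""
    from synthscreen.chem_space import build_mel, enumerate_at

    out = set()

    def rec(frag):
        if not frag.remaining_caps:
            out.add(frag.canonical_smiles)
            return
        for child in enumerate_at(frag, frag.remaining_caps[0], lib):
            rec(child)

    for frag in build_mel(lib):
        rec(frag)
    return out
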