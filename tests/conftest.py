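import warnings

import numpy as np
import pytest

from dystromap import deconv as dc
from dystromap import spatial_core as sc
from dystromap import synthgen as sg

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def reference():
    """Default nine-type reference with its planted-marker table."""
    return sg.make_reference(sg.ReferenceConfig(seed=1))


@pytest.fixture(scope="session")
def dys_tissue(reference):
    """One fat-bearing dystrophic tissue with QC'd, normalized expression."""
    ref, marker_table = reference
    cfg = sg.TissueConfig(
        n_rows=16, n_cols=32, fat_patches=((8, 8, 2),), group="DYS", seed=3,
        lr_niche_pairs=(sg.NichePlant("LPL", "LRP1", "adipocytes", "faps"),),
    )
    cm, grid, labels, truth = sg.make_tissue(cfg, ref, marker_table)
    filtered, kept, _ = sc.qc_filter(cm, labels)
    norm = sc.log_normalize(filtered)
    return {
        "counts": cm, "grid": grid, "labels": labels, "truth": truth,
        "filtered": filtered, "norm": norm, "adjacency": sc.hex_neighbors(grid),
    }


@pytest.fixture(scope="session")
def profiles(reference):
    """Marker selection + reference profiles for deconvolution."""
    ref, _ = reference
    markers = dc.select_markers(ref.counts, ref.cell_labels, ref.genes)
    return markers, dc.build_profiles(ref.counts, ref.cell_labels, ref.genes, markers)


@pytest.fixture
def small_grid():
    """A 6x12 full lattice (36 spots)."""
    return sg.full_lattice(6, 12)


def zone_label_ok(zone: str, label: str) -> bool:
    """Does an annotation label match the generating zone?"""
    if zone == "fat":
        return label == "Fat"
    if zone == "ring":
        return label == "ConnectiveTissue"
    return label in ("TypeI", "TypeIIa", "TypeIIx", "MuscleUntyped")
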