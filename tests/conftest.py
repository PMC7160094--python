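import numpy as np
import pytest

from bronchotaper.tree_model import Branch, SubjectRecord, Tree


def straight_branch(branch_id, parent_id, generation, start, direction,
                    length, inner, outer=None, step=0.5):
    """Straight branch with constant or callable diameter profiles."""
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    grid = np.arange(0.0, length + step / 2, step)
    pts = np.asarray(start, dtype=float) + grid[:, None] * direction
    inner_d = inner(grid) if callable(inner) else np.full(len(grid), float(inner))
    if outer is None:
        outer_d = inner_d * 1.3
    else:
        outer_d = outer(grid) if callable(outer) else np.full(len(grid), float(outer))
    return Branch(branch_id, parent_id, generation, pts, inner_d, outer_d, arc=grid)


def two_branch_subject(parent_inner=5.0, child_inner=4.0):
    """Smallest legal subject: one parent-child airway pair with a
    translated companion artery for each branch."""
    parent = straight_branch("p", None, 0, (0, 0, 0), (0, 0, -1), 10.0, parent_inner)
    child = straight_branch("c", "p", 1, (0, 0, -10), (0.5, 0, -1), 8.0, child_inner)
    airway = Tree("airway", {"p": parent, "c": child}, "p")
    artery_branches = {}
    for b in (parent, child):
        artery_branches["A" + b.branch_id] = Branch(
            "A" + b.branch_id,
            None if b.parent_id is None else "A" + b.parent_id,
            b.generation,
            b.points + np.array([0.0, 2.0, 0.0]),
            np.full(len(b), np.nan),
            b.outer.copy(),
            arc=b.arc.copy(),
        )
    artery = Tree("artery", artery_branches, "Ap")
    return SubjectRecord(
        subject_id="fixture",
        airway_tree=airway,
        artery_tree=artery,
        lung_volume=4.0,
        phenotype="control",
    )


@pytest.fixture
def minimal_subject():
    return two_branch_subject()


@pytest.fixture
def clean_params():
    """Noise-free generator settings with uniform tapering (t=1 %/mm,
    b=20 %) at exactly the 4-L reference volume."""
    from bronchotaper.synthetic_data import GeneratorParams

    return GeneratorParams(
        n_generations=5,
        intra_taper_mean=1.0,
        intra_taper_sd=0.0,
        intra_subject_sd=0.0,
        inter_taper_mean=20.0,
        inter_taper_sd=0.0,
        inter_subject_sd=0.0,
        diameter_noise_sd=0.0,
        outlier_fraction=0.0,
        lung_volume_L=(4.0, 0.0),
        seed=7,
    )
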