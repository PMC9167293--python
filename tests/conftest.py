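import warnings

import numpy as np
import pytest

from uvpheno.geometry import to_spherical
from uvpheno.pca import fit_pca, pool_spectra, project_cube
from uvpheno.phantom import build_spec, generate_phantom


@pytest.fixture(scope="session")
def phantom_na():
    """One non-aggressive phantom: (cube, annotation, truth), seed 11."""
    return generate_phantom(build_spec("non_aggressive", seed=11))


@pytest.fixture(scope="session")
def fitted_field(phantom_na):
    """(basis, spherical field over PCs 1-2-3, annotation) for the phantom."""
    cube, ann, _ = phantom_na
    basis = fit_pca(pool_spectra([cube], seed=11))
    field = to_spherical(project_cube(cube, basis, (1, 2, 3)))
    return basis, field, ann


def run_biomarker(cube, ann, seed=0):
    """Full pipeline to relative shifts for a single-specimen phantom."""
    from uvpheno.biomarker import per_class_com, relative_shifts

    basis = fit_pca(pool_spectra([cube], seed=seed))
    field = to_spherical(project_cube(cube, basis, (1, 2, 3)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return relative_shifts(per_class_com(field, ann))
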