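import sys
from pathlib import Path
from types import SimpleNamespace

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from eit_fatlayer import (
    FEMOperator,
    build_mesh,
    compute_layers,
    make_domain,
    make_protocol,
    place_electrodes,
    reference_set,
)
from eit_fatlayer.config import load_profile
from eit_fatlayer.pipeline import Pipeline


def make_setup(kind="disk", h=0.6, E=10, arc_span=0.5, plate_span_cm=None,
               width=1.0, I=1.0, d0=0.3, L=15, roi=None, **domain_params):
    """Assemble a ready-to-solve context on one mesh."""
    domain = make_domain(kind, **domain_params)
    if plate_span_cm is not None:
        arc_span = plate_span_cm / domain.perimeter
    electrodes = place_electrodes(domain, E, arc_span, width)
    mesh = build_mesh(domain, electrodes, h, d0=d0, n_layers=L)
    protocol = make_protocol(E, I)
    op = FEMOperator(mesh, protocol)
    partition = compute_layers(mesh, d0, L, roi=roi)
    ref = reference_set(op)
    return SimpleNamespace(
        domain=domain, electrodes=electrodes, mesh=mesh, protocol=protocol,
        op=op, partition=partition, ref=ref,
    )


@pytest.fixture(scope="session")
def disk():
    """Coarse disk context shared by solver-level tests."""
    return make_setup()


@pytest.fixture(scope="session")
def tiny_disk():
    """Very coarse disk for dataset-generation tests."""
    return make_setup(h=1.2)


@pytest.fixture(scope="session")
def study():
    """The reduced circular-model study: corpus simulated and network trained
    under the shipped quick profile.  Shared by the end-to-end tests."""
    pipe = Pipeline(load_profile("quick"))
    ds = pipe.build_dataset()
    weights, history = pipe.fit(ds)
    return SimpleNamespace(pipe=pipe, dataset=ds, weights=weights,
                           history=history)


@pytest.fixture(scope="session")
def weights_orig(study):
    """Companion network trained on raw (un-normalized) voltages, used by the
    normalization ablation; same architecture and budget as the main model."""
    from eit_fatlayer.mlp import train

    kwargs = study.pipe.train_kwargs()
    kwargs.update(input_clip=None)
    weights, _ = train(
        study.dataset.inputs_raw, study.dataset.targets,
        study.pipe.mlp_config(), provenance=study.dataset.provenance,
        input_kind="raw", **kwargs,
    )
    return weights
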