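"""Train a small fat-thickness estimator end to end (a few minutes on 1 CPU).

Uses a deliberately thinned corpus (all 91 layer partitions, three muscle
values, one background value) and a short training budget, then
reconstructs phantoms of known fat thickness. This demonstrates the
pipeline mechanics; the shipped `quick`/`paper` profiles define the actual
study conditions.
"""

import numpy as np

from eit_fatlayer import (
    MLPConfig,
    enumerate_specs,
    generate_dataset,
    reconstruct,
    spec_to_field,
)
from eit_fatlayer.dataset import LayeredConductivity
from eit_fatlayer.mlp import train

# -- assemble the study context (disk, electrodes, mesh, reference) -------
from eit_fatlayer import (
    FEMOperator, build_mesh, compute_layers, make_domain, make_protocol,
    place_electrodes, reference_set,
)

domain = make_domain("disk", radius=10.0)
electrodes = place_electrodes(domain, E=10, arc_span=0.5, width=1.0)
mesh = build_mesh(domain, electrodes, h=0.6)
op = FEMOperator(mesh, make_protocol(10, 1.0))
partition = compute_layers(mesh, d0=0.3, L=15)

specs = enumerate_specs(15, 1.0, np.array([4.0, 6.0, 8.0]), np.array([4.5]))
print(f"simulating {len(specs)} layered specifications...")
ds = generate_dataset(op, partition, specs, seed=1)

print("training the inverse network (reduced budget)...")
weights, history = train(
    ds.inputs, ds.targets, MLPConfig.default(1260, 15, seed=1),
    epochs=600, patience=600, lr_decay_every=150, select="final",
    input_transform="whiten", input_clip=(0.0, 20.0),
    provenance=ds.provenance,
)
print(f"final training loss {history.train_loss[-1]:.3f} "
      f"after {history.epochs[-1]} epochs")

ref = reference_set(op)
print("\ntrue fat  estimated fat  (cm)")
for l_f in (2, 5, 7, 10):
    spec = LayeredConductivity(l_f, 14, 1.0, 6.0, 4.5)
    field, _ = spec_to_field(spec, partition)
    res = reconstruct(op.simulate(field), ref, weights)
    print(f"   {spec.fat_thickness(0.3):4.1f}      "
          f"{res.fat_thickness_cm if res.fat_thickness_cm else float('nan'):4.1f}")
print("\nestimates are class decisions quantized to the 0.3 cm layer depth")
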