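"""Generate a labelled phantom cohort and check its planted class contrast.

Class-1 subjects carry focal intensity deficits (ellipsoids of reduced
signal) on a shared smooth baseline; every subject is independently
jittered and noised.  The printed contrast should match the requested
effect size to within Monte-Carlo error.
"""

import numpy as np

from slicegru.synthetic import PhantomSpec, generate_dataset

spec = PhantomSpec(shape=(48, 48, 48), n_per_class=30, effect_size=0.8, noise_sd=0.3, seed=7)
ds = generate_dataset(spec)

means = np.array([v.data[t].mean() for v, t in zip(ds.volumes, ds.region_truth)])
contrast = means[ds.labels == 0].mean() - means[ds.labels == 1].mean()

print(f"subjects: {len(ds.volumes)} ({spec.n_per_class} per class), shape {spec.shape}")
print(f"mean intensity inside planted regions, class 0: {means[ds.labels == 0].mean():.3f}")
print(f"mean intensity inside planted regions, class 1: {means[ds.labels == 1].mean():.3f}")
print(f"estimated class contrast: {contrast:.3f} (planted effect size {spec.effect_size})")
print("-> the deficit the classifier must find is localised in ds.region_truth")
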