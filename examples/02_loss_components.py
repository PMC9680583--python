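"""Evaluate each loss term of the three objectives on transparent inputs.

The adversarial terms are least-squares on sigmoid patch scores; cycle and
identity terms are mean absolute differences; the PatchNCE term is a
temperature-scaled cross-entropy (tau = 0.07) that matches an output patch
to the input patch at the same location against the other locations of the
same image.
"""

import numpy as np

from sctsynth.losses import (LossWeights, cyclecut_generator_objective,
                             lsgan_dis_loss, lsgan_gen_loss,
                             nce_cross_entropy)

print(f"generator fooled perfectly, D(G(x)) = 1:  "
      f"loss = {lsgan_gen_loss(np.array([1.0])):.3f}")
print(f"undecided discriminator, D = 0.5:         "
      f"loss = {lsgan_gen_loss(np.array([0.5])):.3f}")
print(f"perfect discriminator (real 1, fake 0):   "
      f"loss = {lsgan_dis_loss(np.array([1.0]), np.array([0.0])):.3f}\n")

uniform = nce_cross_entropy(0.3, [0.3] * 255, tau=0.07)
print(f"PatchNCE, positive indistinguishable from 255 negatives: "
      f"{uniform:.4f} = log 256 (chance level)")
confident = nce_cross_entropy(1.0, [0.0], tau=0.07)
print(f"PatchNCE, perfect positive vs one orthogonal negative:   "
      f"{confident:.2e} (near zero)\n")

parts = dict(adversarial_a=1.0, adversarial_b=1.0, cycle_mri=0.1,
             cycle_ct=0.1, identity_ct=0.2, identity_mri=0.2,
             nce_1=1.0, nce_2=1.0, nce_3=1.0, nce_4=1.0)
rep = cyclecut_generator_objective(parts, LossWeights())
print("combined objective with alpha=10, beta=5, eta=1 on the components")
for name, value in rep.components.items():
    print(f"  {name:14s} {value:.3f}")
print(f"  total          {rep.total:.3f}   "
      "(= 2 adversarial + 10*0.2 cycle + 5*0.4 identity + 4 contrastive)")
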