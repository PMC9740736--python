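"""The attention-separation loss and what minimising it does.

Prints the loss on three analytic fixtures, then runs plain gradient
descent on the separation penalty from a nearly-collapsed 2-head fixture
and reports how fast the heads decorrelate.  The loss value lives in
[-(h-1)/h, 0]: -0.5 means two heads are perfectly parallel (collapsed),
0 means every pair is orthogonal (fully dispersed).
"""

import numpy as np

from plantseg3d import separation_loss, separation_penalty
from plantseg3d.autodiff import Tensor

f = np.array([[1.0, 2.0], [3.0, 4.0]])
print("identical heads   :", separation_loss([f, f.copy()]).item())
print("orthogonal heads  :", separation_loss([np.array([1.0, 0.0]),
                                              np.array([0.0, 1.0])]).item())
heads3 = [np.array([1.0, 0.0]), np.array([1.0, 1.0]) / np.sqrt(2),
          np.array([0.0, 1.0])]
print("3 heads at 45 deg :", round(separation_loss(heads3).item(), 6))

rng = np.random.default_rng(0)
base = rng.normal(size=(4, 6))
base /= np.linalg.norm(base)
pert = base + 0.01 * rng.normal(size=(4, 6))
pert /= np.linalg.norm(pert)
heads = [Tensor(base.copy(), requires_grad=True),
         Tensor(pert, requires_grad=True)]


def abs_cos():
    a, b = heads[0].data.ravel(), heads[1].data.ravel()
    return abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))


print(f"\ndescent on the separation penalty (start |cos| = {abs_cos():.4f}):")
for step in range(500):
    loss = separation_penalty(heads)
    for t in heads:
        t.grad = None
    loss.backward()
    for t in heads:
        t.data -= 0.3 * t.grad
    if step % 5 == 0 or abs_cos() < 0.05:
        print(f"  step {step:3d}  |cos| = {abs_cos():.4f}")
    if abs_cos() < 0.05:
        print(f"heads decorrelated (|cos| < 0.05) after {step + 1} steps")
        break
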