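"""The SHG preprocessing recipe: clip -> blur -> rolling-ball.

Renders a small fibrous stack, adds a synthetic slowly varying
background, and shows how each stage changes the intensity statistics.
The rolling-ball stage removes the additive background while leaving
the fiber signal nearly untouched.
"""

import numpy as np

from fiberweave import PhantomTruth, ShgStack, gen_fiber_stack
from fiberweave import clip_range, gaussian_blur, rolling_ball_subtract

truth = PhantomTruth(n_fibers=30, intensity_scale=2500.0, seed=3)
stack, fibers, _ = gen_fiber_stack(truth, shape_px=(2, 256, 256))

# superimpose a smooth illumination gradient (what the ball removes)
yy = np.linspace(0, 800, 256)[:, None]
biased = ShgStack(data=stack.data + yy, voxel_um=stack.voxel_um)

s = clip_range(biased)                 # display range (0, 4000)
s = gaussian_blur(s, sigma_px=0.5)     # sigma = 0.5 px
s = rolling_ball_subtract(s, radius_px=40)

for label, arr in [("raw+gradient", biased.data), ("processed", s.data)]:
    print(f"{label:14s} min {arr.min():7.1f}  median {np.median(arr):7.1f}  "
          f"max {arr.max():7.1f}")
print("\nprocessing log:")
for entry in s.processing_log:
    print("  ", entry)
print("\nAfter subtraction the off-fiber median drops to ~0 while the "
      "on-fiber peak stays near the generator's intensity scale.")
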