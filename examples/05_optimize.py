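"""The barnacle-swarm optimizer and its fitness-driven random number.

EIGBO-RE replaces the uniform random number h of the baseline (GBOA) with
h = Currentfit^2 / (Worstfit^2 + Bestfit + Currentfit^2 - Meanfit), coupling
each member's step geometry to how good it currently is. Both variants are
run on the 4-D sphere at the standard settings (population 10, 50 iterations).
"""

import numpy as np

from pestpyramid import Gene, SearchSpace, compute_h, objective_jk, optimize

print(f"h at the all-equal fixed point: {compute_h(2.0, 2.0, 2.0, 2.0)}")
print(f"h for current=2 best=1 worst=4 mean=2.5: {compute_h(2, 1, 4, 2.5):.6f}")
print(f"objective JK at accuracy 0.9672, IoU 0.8: "
      f"{objective_jk(0.9672, 0.8):.4f}  (= 1/acc + 1/IoU, minimized)\n")

space = SearchSpace(genes=tuple(Gene(f"x{i}", "real", -5, 5) for i in range(4)))
sphere = lambda p: float((p ** 2).sum())
for variant in ("eigbo_re", "gboa"):
    finals = [optimize(sphere, space, population=10, iterations=50,
                       variant=variant, seed=s)[0].fitness for s in range(5)]
    print(f"{variant:9s} sphere best fitness, median of 5 seeds: "
          f"{np.median(finals):.2e}")
print("(the optimum is 0; lower is better; traces are monotone by elitism)")
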