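"""Both swarm optimizers on the 5-D sphere benchmark f(x) = sum(x^2).

The known optimum is 0 at the origin; the printed best fitness measures
how close each optimizer gets with a population of 30 over 500 iterations.
"""

from strokecad.optim import Bounds, DFOConfig, SBOConfig, idfo_run, sbo_run, sphere

bounds = Bounds.cube(-5.0, 5.0, 5)

idfo = idfo_run(sphere, bounds, DFOConfig(n=30, iterations=500, seed=7))
sbo = sbo_run(sphere, bounds, SBOConfig(n=30, iterations=500, seed=7))

print(f"improved dragonfly: best fitness {idfo.best_fitness:.3e} "
      f"after {idfo.evaluations} objective evaluations")
print(f"satin bowerbird:    best fitness {sbo.best_fitness:.3e} "
      f"after {sbo.evaluations} objective evaluations")
print("both traces are non-increasing (elitism); values below 1e-2 mean the")
print("optimum is located to within ~0.04 per coordinate on a [-5, 5] box")
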