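# hetsis

SIS epidemics with **heterogeneous recovery rates** on networks: exact
stochastic simulation and spectral mean-field theory.

Most network epidemic models treat all individuals as recovering at the
same rate and place all heterogeneity in the contact structure. Real
infectious periods vary between individuals — biology, demography, access
to care — and that *dynamical* heterogeneity shifts the epidemic threshold
just as structural heterogeneity does. `hetsis` is a toolkit for studying
the susceptible–infected–susceptible (SIS) process when each node *i*
recovers at its own Poisson rate δᵢ and transmits along each edge at rate
λᵢⱼ (uniform λ, or λ/kᵢ for the contact process).

## Theory in brief

In the quenched mean-field (QMF) approximation the infection
probabilities yᵢ = ⟨Yᵢ⟩ obey

    dyᵢ/dt = −δᵢ yᵢ + (1 − yᵢ) Σⱼ λᵢⱼ Aᵢⱼ yⱼ

and the epidemic threshold is governed by the matrix
**Q = Δ⁻¹(A∘W)** (Δᵢᵢ = δᵢ, Wᵢⱼ = λᵢⱼ), whose entries are the expected
number of contacts a node makes before recovering:

    λ_c = 1 / Λ_max(Q)

Two a-priori bounds accompany the prediction: the norm sandwich
min(δᵢ)/Λ_max(A) ≤ λ_c ≤ max(δᵢ)/Λ_max(A), and the Gershgorin bound
Λ_max(Q) ≤ max_i kᵢ/δᵢ. The latter explains the package's headline
phenomenology: choosing δᵢ = kᵢ pins the threshold of *any* power-law
network at exactly 1 (structure–dynamics cancellation), while a
heavy-tailed rate assignment on a homogeneous graph can make the
threshold vanish with system size.

The stochastic side is an exact Gillespie simulation of the Markov chain
with **quasistationary (QS) conditioning**: when the epidemic dies out the
state is replaced by a configuration drawn from a store of previously
visited active configurations, so the order parameter ρ = ⟨n_I⟩/N and the
susceptibility χ = (⟨n_I²⟩ − ⟨n_I⟩²)/⟨n_I⟩ are measurable at finite size;
the χ peak locates the transition.

## Worked example

```python
import hetsis as h

net, _ = h.giant_component(h.generate_er(2000, 10, seed=42))
rates = h.inverse_gamma_rates(net.n_nodes, alpha=2.5, seed=7)  # unit mean
rep = h.critical_point(net, rates)
print(rep.to_dict())

res = h.lambda_sweep(
    net, rates, "uniform",
    qs_params=dict(relax_time=400, avg_time=1200, p_store_update=0.2,
                   n_store=10, init_fraction=0.02),
    seed=0,
)
print(res.lambda_peak, res.qmf_prediction.critical_point)
```

prints (numbers from this exact run):

```
{'lambda_max': 18.726864, 'critical_point': 0.053399,
 'bound_low': 0.012412, 'bound_high': 1.321675,
 'inf_norm_bound': 89.912912, 'ipr': 0.004309}
0.0614  0.0534
```

Reading: with strongly heterogeneous recovery (inverse-gamma shape
α = 2.5, unit mean), the predicted threshold 0.053 sits well **below** the
homogeneous-rate value 1/Λ_max(A) ≈ 0.09 — heterogeneous recovery makes
the population more vulnerable — and the simulated susceptibility peak
(0.061) lands close to the spectral prediction, between the sandwich
bounds. The IPR ≈ 4/N indicates a delocalized leading eigenvector.

The same protocols are scriptable from the shell:

```bash
hetsis qmf --kind er --n 2000 --mean-degree 10 --rates inverse_gamma --alpha 2.5 --seed 42
hetsis simulate --kind er --n 2000 --rates inverse_gamma --alpha 2.5 --lam 0.06 --seed 0
hetsis sweep config.yaml --out curve.csv     # YAML-driven chi(lambda) sweep
hetsis alpha-scan config.yaml                # threshold vs inverse-gamma shape
hetsis fss config.yaml                       # finite-size analysis
```

A sweep YAML looks like:

```yaml
seed: 0
network: {kind: er, n: 2000, mean_degree: 10}
rates: {scheme: inverse_gamma, alpha: 2.5}
qs_params: {relax_time: 400, avg_time: 1200, p_store_update: 0.2,
            n_store: 10, init_fraction: 0.02}
```

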