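# aptrans

**Quantitative translation of ion-channel drug effects between cardiac
species.**

Drug safety screening routinely measures how a compound changes the
ventricular action potential (AP) of animal cardiomyocytes, but animal and
human APs differ because the mix of membrane currents differs — the same
channel block can lengthen a dog AP by 18% and a human AP by 40%.  What *is*
conserved is the channel protein itself: if a blocker halves the conductance
of a single channel at concentration IC50 in an animal membrane, it does the
same in a human membrane.  `aptrans` exploits that invariance:

1. **Model** each species' ventricular AP with one shared set of channel
   kinetics and species-specific effective maximal conductances
   `I_x = g_x · o_x · (v − E_x)` (a GHK-style driving force for the L-type
   calcium current; standard saturation forms for the Na⁺/K⁺ pump, the
   Na⁺/Ca²⁺ exchanger and the sarcolemmal Ca²⁺ pump).  Human, dog,
   zebrafish, rabbit and guinea-pig parameterizations ship with the package;
   the zebrafish additionally carries a T-type calcium current.
2. **Block** channels with the Hill-1 conductance model
   `g_x(D) = g_x / (1 + ε_x D)`, `ε = 1/IC50`, so dose = IC50 halves the
   current exactly.
3. **Invert** dose–response AP-biomarker data (APD20…APD90, v_min, v_max,
   optionally dv/dt_max) for per-current adjustment factors λ and the drug's
   ε per channel, by minimizing the weighted relative-residual cost
   `H(λ, ε) = Σ_d Σ_j w_{d,j} H_j(λ, ε, D_d)²` with a continuation scheme of
   randomized Nelder–Mead restarts.
4. **Translate**: carry ε̂ (species-invariant) into the target species'
   model — λ̂ stays behind, it describes the individual source cell — and
   report predicted biomarker changes per dose.

A synthetic-data module generates ground-truthed datasets (known λ*, ε*,
optional observation noise) so every stage is testable without experimental
recordings.

## Worked example

Estimate a drug effect on zebrafish and predict the human response.  The
synthetic "experiment": zebrafish with I_Na, I_CaL and I_Kr scaled ×1.2
(the hidden individual), dosed with a compound that blocks I_Na and I_CaL
by 50% at 1 µM.

```python
from aptrans import apmodel, species_defaults
from aptrans.synthetic import SyntheticDesign, drug_for_block, generate_dataset
from aptrans.inversion import InversionConfig, invert
from aptrans.translation import translate_drug, summarize_table

zf = species_defaults("zebrafish")
drug = drug_for_block("na-cal-blocker", {"I_Na": 0.5, "I_CaL": 0.5}, dose=1.0)
design = SyntheticDesign(base_species=zf, true_drug=drug, doses=(0.0, 1.0),
                         perturbation={"I_Na": 1.2, "I_CaL": 1.2, "I_Kr": 1.2})
dataset, truth = generate_dataset(design)

cfg = InversionConfig(free_epsilons=("I_Na", "I_CaL", "I_Kr"),
                      free_lambdas=("I_Na", "I_CaL", "I_Kr"),
                      continuation_iterations=4, guesses_per_iteration=20,
                      nm_iterations=15, include_dvdt_term=True, rng_seed=1)
result = invert(dataset, cfg, zf)

report = translate_drug(result, species_defaults("human"), [1.0])
print(summarize_table(report, ["apd50", "apd90", "dvdt_max"]))
```

Output:

```
                 control    1 uM
apd50 (ms)         222.9   -4.4%
apd90 (ms)         316.5   -3.9%
dvdt_max (mV/ms)    84.2  -50.3%
```

Reading: the human control model has APD50 ≈ 223 ms and APD90 ≈ 317 ms at
1 Hz; the translated drug effect shortens the human APD50 by ~4.4% and
roughly halves the upstroke velocity — within half a percentage point of
simulating the human model with the true ε (−4.9% and −50.9%), even though
the estimate came entirely from zebrafish data.  The recovered per-channel
block at 1 µM was 49.4% (I_Na), 49.7% (I_CaL) and 1.5% (I_Kr, correctly
identified as untargeted).

The same objects drive the command line:

```bash
aptrans simulate --species human --out human.csv
aptrans synth --design design.yaml --out dataset.json
aptrans invert --dataset dataset.json --config inversion.yaml --out fit.json
aptrans translate --result fit.json --target human --doses 0,1 --out report.json
aptrans report --report report.json --markdown
```

## Scope and caveats

Concentrations are fixed (no intracellular Ca²⁺/Na⁺/K⁺ dynamics), the block
model is conductance-only with Hill coefficient 1, and drug targets must be
named a priori.  A drug effect on a current that is negligible in the
source species cannot be estimated from that species — the inversion warns
rather than guesses.  See `docs/methods.md` for the model equations,
calibration choices and known limitations.
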