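# molgen

De novo small-molecule design with a latent-space feedback GAN and
multi-objective Pareto selection.

## The problem

Generative models for drug discovery must produce molecules that are valid,
novel, synthesizable and potent against a target — several objectives at
once.  GANs cannot be trained directly on SMILES strings because sampling
discrete tokens blocks backpropagation.  `molgen` implements a pipeline that
sidesteps this and then *steers* the generator toward desirable chemistry:

1. **Sequence autoencoder** — a bidirectional-LSTM encoder maps a tokenized
   SMILES `s` to a continuous context vector `C ∈ R^d` (stereochemistry and
   charge annotations like `[C@@H]`, `[N+]` are single tokens, so they
   survive the round trip); an LSTM decoder trained with teacher forcing
   maps `C` back to `s`.
2. **WGAN-GP** — critic `D` and generator `G` are dense networks over the
   latent space, trained with the gradient-penalty Wasserstein loss

       L = E[D(G(z))] − E[D(x)] + λ·E[(‖∇_x̂ D(x̂)‖₂ − 1)²],
       x̂ = ε·G(z) + (1−ε)·x,  ε ~ U(0,1).

3. **Feedback loop** — each epoch, sampled molecules are scored with a
   multi-objective score vector (e.g. `(pIC50(m), −SAS(m))`), ranked by
   NSGA-II domination counts, and the Pareto-best replace the worst members
   of the GAN's 5000-molecule training pool; the generated distribution
   drifts toward the target region.
4. **Evaluation** — validity / uniqueness / novelty, internal and external
   Tanimoto diversity on ECFP4 fingerprints
   (`Div(A,B) = mean over pairs of (1 − T_s)`), and the distribution-learning
   score `S = (1/k) Σ_i exp(−D_KL,i)` over a 10-feature descriptor panel.

It is aimed at method developers: everything runs at desk scale on a single
CPU with a built-in toy-molecule generator and a deterministic surrogate
activity oracle, and scales by configuration.  A pIC50 QSAR regressor
(`molgen.predictor`) plugs in wherever the surrogate is used, given a
`smiles,pIC50` CSV.

The neural models run on a compact numpy autodiff engine included in the
package (`molgen.autodiff`, `molgen.nn`) with double-backprop support for
the gradient penalty; there is no deep-learning framework dependency.

## Worked example

```python
from molgen import (ToyLibraryConfig, generate_toy_library, tokenize,
                    surrogate_activity, score_vector, rank_population,
                    select_best, ObjectiveSet)

library = generate_toy_library(ToyLibraryConfig(n_molecules=6, seed=4))
objective = ObjectiveSet("SURR_SAS", (("pIC50", +1), ("SAS", -1)))
scores = [score_vector(rec, objective, surrogate_activity) for rec in library]
ranking = rank_population(scores)
for rec, sv, c in zip(library, scores, ranking.domination_count):
    print(f"{rec.smiles:<22} tokens={len(tokenize(rec.smiles)):>2} "
          f"pIC50={sv.values[0]:.2f} SAS={-sv.values[1]:.2f} dominated_by={c}")
best = select_best(scores, 2)
print("selected:", [library[i].smiles for i in best])
```

prints

```
CC(F)N(N)[C@@](F)(Cl)CCl tokens=18 pIC50=6.57 SAS=5.00 dominated_by=1
OC1(Cl)C(Cl)C2NC2SC1(Cl)Cl tokens=22 pIC50=8.74 SAS=5.76 dominated_by=0
FC1C2C[C@@H]12         tokens= 9 pIC50=5.93 SAS=3.83 dominated_by=0
CC1(F)CCOC(F)C1CCl     tokens=17 pIC50=7.20 SAS=4.92 dominated_by=0
N[C@@H]1CNNCC(=C(O)Cl)C1 tokens=18 pIC50=6.49 SAS=4.92 dominated_by=0
C1=NN2OCSCON2S1        tokens=15 pIC50=6.78 SAS=5.78 dominated_by=2
selected: ['OC1(Cl)C(Cl)C2NC2SC1(Cl)Cl', 'CC1(F)CCOC(F)C1CCl']
```

Reading this: each molecule gets a surrogate potency (pIC50-like, 4–10) and
an Ertl synthetic-accessibility score (1 easy … 10 hard); the score vector
`(pIC50, −SAS)` puts both in a maximization convention.  `dominated_by` is
the NSGA-II domination count — 0 marks the Pareto front (no other molecule
is at least as potent *and* easier to make).  `select_best` walks the fronts
and breaks ties by the first objective, so the two selected molecules are
the front members with the highest potency.

The full pipeline — train the autoencoder, train the WGAN-GP on its
latents, then run the feedback loop — is wired the same way; see
`scripts/acceptance.py` for a complete, runnable end-to-end driver and
`docs/methods.md` for the models, parameters and assumptions.  A CLI
(`molgen preprocess / train-ae / train-gan / train-predictor / select /
evaluate`) wraps the file-based steps.

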