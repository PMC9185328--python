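# troposearch

Gorilla-troops hyperparameter search for transfer-learning image
classifiers, with MRI-style preprocessing and a confusion-count metrics
suite.

## The problem

Choosing training hyperparameters for a CNN classifier — loss function,
batch size, dropout, optimizer, how much of a pretrained backbone to
unfreeze, whether and how to augment — is a black-box optimization problem.
`troposearch` solves it with the **artificial gorilla troops optimizer
(GTO)**, a swarm metaheuristic: a troop of N candidate solutions
("gorillas") evolves in `[0, 1]^16`, the incumbent best is the
"silverback", and each iteration alternates an exploration move, a greedy
fitness-based replacement, an exploitation move, and a second replacement.
The package was built around Alzheimer's-stage classification from brain
MRI slices (4-class dementia-grade and 3-class NC/MCI/AD settings), but
nothing in it is specific to that task.

Each solution is a vector `x ∈ [0, 1]^16`. Element `j` is decoded against
its hyperparameter domain: a list-like domain of length `L` is indexed with
`idx = clamp(⌈x_j · L⌉, 1, L)` (1-based), and a continuous range `[lo, hi]`
interpolates `lo + x_j (hi − lo)`. For example, `x = 0.75` against the
batch-size grid `4, 8, …, 48` (12 values) gives index 9, i.e. batch size 36.
The brightness augmentation range is an ordered pair and consumes two
elements, which is why 15 hyperparameters occupy 16 slots.

The troop updates are, per member `i` (with decaying coefficient
`C = (cos 2r₄ + 1)(1 − t/T)` and `L = C·l`, `l ~ U(−1,1)`):

* exploration — migration to an unknown place with probability `p`, a move
  toward a random troop member, or a move relative to a known place;
* exploitation — follow the silverback (`C ≥ w`) or the competition-for-
  adult-females move (`C < w`), which jumps around the silverback with an
  impact force `Q ∈ [−1, 1]` and violence coefficient `A = β·E`.

Fitness of a solution is `1 − accuracy` after decoding it, training a
classifier for a fixed number of epochs, and evaluating. The built-in
trainable model (`toy_cnn`) is a compact numpy-trained convolutional
network that honours every searched hyperparameter: the six losses
(crossentropy, KL divergence, Poisson, and the hinge family), the eleven
optimizers (Adam, NAdam, AdaGrad, AdaDelta, AdaMax, RMSProp plain and
centered, SGD plain and Nesterov, Ftrl, Adam AMSGrad), dropout, and the
fine-tuning learn ratio (trailing percentage of backbone layers left
trainable). ImageNet-pretrained backbones can be attached through a builder
registry.

Around the optimizer sit the standard pipeline stages: signal-to-noise
cleaning (images with `mean/std < 1.15` are discarded), bicubic resizing to
`128×128×3`, categorical label encoding, four pixel-scaling techniques
(normalize, standardize, min-max, max-abs), a stratified 85/15
train-test split, and augmentation-based class balancing. A synthetic
brain-image generator (elliptical cortex ring, class-dependent ventricle
size, injectable pure-noise images) makes the whole pipeline testable on a
laptop with no downloads.

## Worked example

```python
from troposearch import RunConfig, run

config = RunConfig(
    synthetic=dict(K=3, n_per_class=20, image_size=(64, 64),
                   noisy_fraction=0.1, seed=1),
    population=4, iterations=2, epochs=1,
    input_size=(64, 64, 3), seed=0, output_dir="demo_run",
)
result = run(config)["toy_cnn"]
print("best fitness:", result.best_fitness)
print("history:", result.history["best_fitness"].tolist())
print("best config:", result.best_config["loss_name"],
      result.best_config["batch_size"], result.best_config["optimizer_name"])
```

prints

```
best fitness: 0.16666666666666663
history: [0.4814814814814815, 0.40740740740740744, 0.16666666666666663]
best config: Categorical Crossentropy 4 SGD Nesterov
```

The history is the best `1 − accuracy` after the initial population and
each of the two iterations: the troop improved from 52% to 83% accuracy on
the 3-class synthetic task (confusion counts TP=45, TN=99, FP=9, FN=9,
micro-averaged over classes; MCC 0.75). Artifacts — the decoded best
configuration, the full metric report, a per-iteration history CSV, an
evaluation ledger, and a resume checkpoint — are written under
`demo_run/toy_cnn/`.

The same loop is available from a shell:

```bash
troposearch synth -k 4 -n 25 --noisy-fraction 0.1 data/
troposearch clean data/                 # SNR report at the 1.15 threshold
troposearch optimize --dataset data/ --population 10 --iterations 10
troposearch evaluate counts.json        # metric suite from saved counts
```

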