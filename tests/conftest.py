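import numpy as np
import pytest
from hypothesis import settings

from polypseg import (ArchitectureSpec, PhantomSpec, PostprocessSpec,
                      TrainingSpec, build_network, confusion_counts, dice,
                      generate_corpus, postprocess, predict, train)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_corpus():
    """Eight 3-frame sequences of 64x64 phantoms (cheap, shared)."""
    spec = PhantomSpec(image_height=64, image_width=64, n_sequences=8,
                       frames_per_sequence=3, polyp_radius_range=(8, 16),
                       seed=123)
    return generate_corpus(spec)


@pytest.fixture(scope="session")
def small_arch():
    return ArchitectureSpec(input_size=(64, 64), dropout_rate=0.1)


@pytest.fixture(scope="session")
def small_net(small_arch):
    """Untrained 64x64 network (random weights)."""
    return build_network(small_arch, seed=0)


@pytest.fixture(scope="session")
def overfit_run():
    """Train on a single phantom until it is memorized.

    A capacity sanity check shared by the training, inference and acceptance
    tests: one 128x128 phantom, 200 iterations of Adam.  Returns the
    trained network, the sample, the loss trace and the post-processed Dice
    on the training frame.
    """
    pspec = PhantomSpec(image_height=128, image_width=128, n_sequences=1,
                        frames_per_sequence=1, polyp_radius_range=(25, 25),
                        seed=5)
    sample = generate_corpus(pspec)[0]
    arch = ArchitectureSpec(input_size=(128, 128), dropout_rate=0.1)
    net = build_network(arch, seed=0)
    tspec = TrainingSpec(epochs=200, initial_learning_rate=1e-3,
                         decay_every=100, decay_factor=0.5, batch_size=1, seed=0)
    trace = train(net, [sample], tspec)
    prob = predict(net, sample.image)
    pred = postprocess(prob, PostprocessSpec(opening_radius=0))
    d = dice(confusion_counts(pred, sample.mask))
    return {"net": net, "sample": sample, "trace": trace, "dice": d}
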