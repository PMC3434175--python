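"""Transfer of training: does an implicitly learnt audio cue survive a change
of environment?

Pilots are tested without the motion platform before and after training.
Training raises their ``audio_skill`` — the degree to which the turbine sound
is converted into a forward-model velocity estimate.  A paired one-sided
t-test compares matched pre/post conditions, and the learning-inclusion
filter (a straight-line fit over the four training phases; minimum fitted
improvement 0.15 ft) screens out non-learners.
"""

import numpy as np

from cuefidelity import (
    ControllerSpec,
    CueChannelParams,
    HeaveParams,
    TargetPathSpec,
    fly_tracking_run,
    learning_filter,
    paired_compare,
    target_path,
)

path = target_path(TargetPathSpec(duration=60.0, dt=0.01, seed=12))
cues = CueChannelParams()


def test_run(seed, skill):
    return fly_tracking_run(
        HeaveParams(zw=-0.1), cues, path,
        ControllerSpec(seed=seed, audio_skill=skill),
        motion_on=False, turbine_on=True,
    ).median_abs_error


pre = np.array([test_run(2000 + s, 0.0) for s in range(6)])
post = np.array([test_run(3000 + s, 0.85) for s in range(6)])
t, df, p = paired_compare(pre, post, alternative="greater")
print(f"pre-training error:  {pre.mean():.2f} ft (se {pre.std(ddof=1)/np.sqrt(6):.2f})")
print(f"post-training error: {post.mean():.2f} ft (se {post.std(ddof=1)/np.sqrt(6):.2f})")
print(f"paired one-sided t-test: t = {t:.2f}, df = {df}, p = {p:.2g}\n")

# learning curves over four training phases (skill grows for a learner)
learner = [test_run(4000, a) for a in (0.0, 0.3, 0.6, 0.85)]
res = learning_filter(learner)
print(f"learner phase errors (ft): {[round(e, 2) for e in learner]}")
print(f"fitted improvement {res.improvement:.2f} ft -> "
      f"{'included' if res.included else 'excluded'}")

non_learner = [test_run(5000 + i, 0.0) for i in range(4)]
res2 = learning_filter(non_learner)
print(f"non-learner phase errors (ft): {[round(e, 2) for e in non_learner]}")
print(f"fitted improvement {res2.improvement:.2f} ft -> "
      f"{'included' if res2.included else 'excluded'}")
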