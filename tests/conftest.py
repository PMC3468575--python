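import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gapscreen import Pose, PoseStack, SimConfig, build_stack

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20120)


@pytest.fixture
def simple_stack():
    """Three-pose stack with scores -10, -4, -2 (gap = -7)."""
    return build_stack("lig", "rec", [
        Pose("p1", -10.0), Pose("p2", -4.0), Pose("p3", -2.0)])


@pytest.fixture
def small_config():
    """Down-scaled simulator config for fast per-test generation."""
    return SimConfig(n_runs=1, poses_per_run=40, n_funnel_poses=5)


def random_stack(rng, n=None, loc=-15.0, scale=3.0, ligand="L", receptor="R"):
    """Random score-only stack (continuous scores, no ties)."""
    n = n or int(rng.integers(5, 50))
    scores = rng.normal(loc, scale, n)
    poses = [Pose(f"p{i:03d}", s) for i, s in enumerate(scores)]
    return build_stack(ligand, receptor, poses)


def stack_from_scores(scores, ligand="L", receptor="R"):
    """Stack built directly from a score list, bypassing deduplication
    (needed for degenerate cases like all-equal scores)."""
    poses = sorted((Pose(f"p{i:03d}", s) for i, s in enumerate(scores)),
                   key=lambda p: (p.score, p.pose_id))
    return PoseStack(ligand, receptor, poses)
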