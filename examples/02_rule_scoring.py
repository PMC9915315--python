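"""Score single posts with the expert rule scorer and show the breakdown.

Six weighted dimensions (attention 0.20, user 0.10, emotion 0.05, words
0.05, address 0.20, contact 0.40) produce a 0-100 usefulness score; a post
is useful iff the score reaches the boundary 40.
"""

from mrim import Microblog, classify_post, extract_features, generate_lexicons

resources = generate_lexicons(seed=0).extraction_resources()

posts = [
    Microblog(id="rescue", text="被困 金水医院 三楼 求救 请联系 13812345678 非常 危险",
              likes=100, comments=50, shares=20, prior_posts=300, followers=40, fans=80),
    Microblog(id="chatter", text="今天 天气 不错",
              likes=2, comments=0, shares=0, prior_posts=50, followers=10, fans=5),
]

for post in posts:
    features = extract_features(post, resources)
    label, score, dims = classify_post(post, features)
    verdict = "USEFUL" if label else "useless"
    print(f"{post.id}: score {score:.2f} -> {verdict}")
    print(f"  A1 attention {dims.a1_attention:6.2f}   A2 user    {dims.a2_user:6.2f}")
    print(f"  A3 emotion   {dims.a3_emotion:6.2f}   A4 words   {dims.a4_words:6.2f}")
    print(f"  A5 address   {dims.a5_address:6.2f}   A6 contact {dims.a6_contact:6.2f}")
    print(f"  features: wc={features.word_count} senti={features.sentiment_value:+.1f} "
          f"addr={features.has_exact_address} contact={features.has_contact}")
    print()

print("a post with contact information alone scores 0.40 x 100 = 40, exactly the boundary;")
print("the rescue post above adds address (20) and attention, putting it far beyond.")
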