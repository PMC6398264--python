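"""Full-text search over clinical notes with Norwegian analysis.

Builds the embedded inverted index over a synthetic corpus and runs a
boolean keyword query restricted to documents of type "andre" (other),
mirroring how a clinician would search an un-searchable note archive.
"""

from carefuse.synthetic_data import generate_keyword_corpus
from carefuse.text_index import analyze, build_index, parse_query

print("analysis chain:", analyze("Blodtrykket er normalt"))
# -> stopword "er" dropped, tokens case-folded and stemmed

docs = generate_keyword_corpus(seed=1, n_matching=36)
index = build_index(docs)

query = parse_query("blod OR bt", doc_type="andre", page_size=5)
page = index.search(query)
print(f'query "blod OR bt" over type "andre": {page.total} documents found')
for r in page.results:
    print(f"  {r.doc_id:10s} score={r.score:.3f}  {r.snippet}")
# Ranking is BM25 relevance damped by document age (half-life 365 days),
# so equally relevant but fresher notes surface first; ** marks matches.
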