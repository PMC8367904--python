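"""Default open word lists for the 31 dictionary-counted style categories.

These lists are compiled from public-domain inventories of English function
words and common emotion/cognition vocabulary. They implement the canonical
schema of :mod:`stylesalience.schema` without any proprietary dictionary
content. Patterns are lowercase; a trailing ``*`` is a prefix wildcard
(``enjoy*`` matches ``enjoy``, ``enjoys``, ``enjoying``). A word may belong
to several categories, as in any hierarchical closed-vocabulary system.

The lists are intentionally compact. They are adequate for the synthetic
corpora this package generates and for demonstration on real text; users
with richer dictionaries (including a licensed LIWC file via
:func:`stylesalience.features.read_liwc_dic`) can substitute their own.
"""

from __future__ import annotations

DEFAULT_CATEGORY_WORDS: dict[str, list[str]] = {
    "funct": [
        "a", "an", "the", "and", "or", "but", "if", "of", "to", "in", "for",
        "on", "with", "at", "by", "from", "as", "that", "this", "these",
        "those", "it", "its", "is", "are", "was", "were", "be", "been",
        "being", "i", "me", "my", "we", "us", "our", "you", "your", "he",
        "him", "his", "she", "her", "they", "them", "their", "not", "no",
        "do", "does", "did", "have", "has", "had", "will", "would", "can",
        "could", "shall", "should", "may", "might", "must", "there", "here",
        "what", "which", "who", "whom", "whose", "all", "some", "any",
    ],
    "i": ["i", "me", "my", "mine", "myself", "i'm", "i'd", "i'll", "i've"],
    "we": [
        "we", "us", "our", "ours", "ourselves", "we're", "we'll", "we've",
        "we'd", "let's", "lets",
    ],
    "you": [
        "you", "your", "yours", "yourself", "yourselves", "you're",
        "you'll", "you've", "you'd", "ya",
    ],
    "shehe": [
        "he", "him", "his", "himself", "she", "her", "hers", "herself",
        "he's", "she's", "he'd", "she'd", "he'll", "she'll",
    ],
    "they": [
        "they", "them", "their", "theirs", "themselves", "they're",
        "they've", "they'll", "they'd",
    ],
    "ipron": [
        "it", "its", "it's", "this", "that", "that's", "these", "those",
        "something", "anything", "nothing", "everything", "somebody",
        "anybody", "nobody", "everybody", "someone", "anyone", "everyone",
        "what", "whatever", "which", "whichever", "stuff", "thing", "things",
    ],
    "article": ["a", "an", "the"],
    "preps": [
        "about", "above", "across", "after", "against", "along", "among",
        "around", "at", "before", "behind", "below", "beneath", "beside",
        "between", "beyond", "by", "despite", "down", "during", "except",
        "for", "from", "in", "inside", "into", "near", "of", "off", "on",
        "onto", "out", "outside", "over", "past", "since", "through",
        "throughout", "till", "to", "toward", "towards", "under", "until",
        "up", "upon", "with", "within", "without",
    ],
    "auxverb": [
        "am", "is", "are", "was", "were", "be", "been", "being", "have",
        "has", "had", "having", "do", "does", "did", "doing", "will",
        "would", "can", "could", "shall", "should", "may", "might", "must",
        "ought", "won't", "wouldn't", "can't", "cannot", "couldn't",
        "shouldn't", "don't", "doesn't", "didn't", "isn't", "aren't",
        "wasn't", "weren't", "haven't", "hasn't", "hadn't", "ain't",
    ],
    "adverb": [
        "very", "really", "quite", "just", "too", "so", "well", "quickly",
        "slowly", "often", "always", "never", "sometimes", "usually",
        "rarely", "almost", "nearly", "completely", "totally", "absolutely",
        "highly", "deeply", "barely", "hardly", "simply", "actually",
        "probably", "perhaps", "maybe", "soon", "already", "still", "yet",
        "again", "also",
    ],
    "conj": [
        "and", "but", "or", "nor", "so", "because", "although", "though",
        "while", "whereas", "unless", "until", "since", "if", "when",
        "whenever", "where", "wherever", "as", "than", "whether",
    ],
    "verb": [
        "go", "goes", "going", "went", "gone", "make", "makes", "making",
        "made", "take", "takes", "taking", "took", "taken", "get", "gets",
        "getting", "got", "gotten", "come", "comes", "coming", "came",
        "see", "sees", "seeing", "saw", "seen", "know", "knows", "knowing",
        "knew", "known", "think", "thinks", "thinking", "thought", "say",
        "says", "saying", "said", "tell", "tells", "telling", "told",
        "want", "wants", "wanted", "need", "needs", "needed", "feel",
        "feels", "felt", "give", "gives", "gave", "given", "find", "finds",
        "found", "work", "works", "worked", "play", "plays", "played",
        "help", "helps", "helped", "talk", "talks", "talked", "look",
        "looks", "looked", "try", "tries", "tried", "use", "uses", "used",
        "call", "calls", "called", "ask", "asks", "asked",
    ],
    "past": [
        "went", "gone", "made", "took", "taken", "got", "gotten", "came",
        "saw", "seen", "knew", "known", "said", "told", "felt", "gave",
        "given", "found", "tried", "used", "was", "were", "had", "did",
        "been", "walked", "talked", "looked", "helped", "played", "worked",
        "asked", "called", "wanted", "needed", "thought", "happened",
    ],
    "present": [
        "am", "is", "are", "go", "goes", "make", "makes", "take", "takes",
        "get", "gets", "come", "comes", "see", "sees", "know", "knows",
        "think", "thinks", "say", "says", "tell", "tells", "want", "wants",
        "need", "needs", "feel", "feels", "give", "gives", "find", "finds",
        "have", "has", "do", "does",
    ],
    "future": [
        "will", "shall", "gonna", "we'll", "i'll", "you'll", "he'll",
        "she'll", "they'll", "it'll", "won't",
    ],
    "quant": [
        "all", "any", "both", "each", "every", "few", "fewer", "least",
        "less", "lot", "lots", "many", "more", "most", "much", "none",
        "plenty", "several", "some", "bunch", "couple", "enough", "extra",
        "half", "whole",
    ],
    "number": [
        "one", "two", "three", "four", "five", "six", "seven", "eight",
        "nine", "ten", "eleven", "twelve", "twenty", "thirty", "hundred",
        "thousand", "million", "first", "second", "third", "once", "twice",
        "single", "double",
    ],
    "time": [
        "time", "times", "today", "tomorrow", "yesterday", "now", "then",
        "when", "soon", "later", "early", "earlier", "late", "morning",
        "evening", "night", "day", "days", "week", "weeks", "month",
        "months", "year", "years", "hour", "hours", "minute", "minutes",
        "moment", "during", "before", "after", "until", "while", "ago",
    ],
    "posemo": [
        "good", "great", "happy", "happiness", "love", "loves", "loved",
        "loving", "nice", "wonderful", "amazing", "awesome", "brilliant",
        "beautiful", "enjoy*", "fun", "funny", "glad", "excellent",
        "fantastic", "lovely", "sweet", "kind", "thank*", "hope*", "joy*",
        "proud", "pleased", "perfect", "best", "better", "excit*", "care",
        "caring", "cared", "support*", "laugh*", "smile*", "hug*",
    ],
    "negemo": [
        "bad", "hate*", "hurt*", "sad", "sadness", "angry", "anger",
        "annoy*", "afraid", "fear*", "worry*", "worried", "terrible",
        "awful", "horrible", "nasty", "upset", "miserable", "cry*",
        "cried", "pain*", "stress*", "guilt*", "shame*", "lonely",
        "depress*", "anxious", "anxiety", "frustrat*", "disappoint*",
        "scared", "scare*", "worst", "worse", "wrong", "problem*",
        "difficult", "struggle*",
    ],
    "swear": [
        "damn", "damned", "hell", "crap", "shit*", "fuck*", "bloody",
        "bastard*", "piss*", "arse*", "ass", "bugger*", "bollocks",
        "wank*",
    ],
    "negation": [
        "no", "not", "never", "none", "nothing", "nobody", "nowhere",
        "neither", "nor", "without", "cannot", "can't", "don't", "won't",
        "isn't", "aren't", "wasn't", "weren't", "didn't", "doesn't",
        "couldn't", "wouldn't", "shouldn't", "haven't", "hasn't", "hadn't",
        "ain't",
    ],
    "assent": [
        "yes", "yeah", "yep", "yup", "ok", "okay", "agree*", "absolutely",
        "definitely", "sure", "indeed", "fine", "alright", "exactly",
        "totally",
    ],
    "insight": [
        "think*", "thought", "know*", "knew", "known", "consider*",
        "understand*", "understood", "realize*", "realise*", "believ*",
        "feel", "feels", "felt", "feeling*", "idea*", "insight*", "aware*",
        "reflect*", "reason*", "learn*", "learnt", "sense", "wonder*",
        "figure*", "notice*",
    ],
    "cause": [
        "because", "cause", "caus*", "since", "hence", "therefore", "thus",
        "why", "effect*", "affect*", "result*", "lead", "leads", "led",
        "depend*", "due", "consequen*", "outcome*", "produce*", "trigger*",
        "basis", "influenc*",
    ],
    "discrep": [
        "should", "would", "could", "ought", "hope*", "wish*", "want*",
        "need*", "expect*", "prefer*", "rather", "instead", "supposed",
        "must", "mustn't", "lack*", "missing", "shouldn't", "wouldn't",
        "couldn't",
    ],
    "tentat": [
        "maybe", "perhaps", "possibly", "probably", "might", "may",
        "seem*", "appear*", "guess*", "suppose*", "sort", "kinda",
        "somewhat", "unsure", "unclear", "vague*", "roughly", "around",
        "about", "almost", "hopefully", "apparently", "presumably",
        "likely", "unlikely", "depends",
    ],
    "incl": [
        "and", "with", "also", "both", "include*", "including", "together",
        "along", "plus", "add", "added", "each", "open", "share*", "join*",
    ],
    "excl": [
        "but", "except", "without", "exclude*", "excluding", "however",
        "although", "though", "either", "or", "else", "rather", "unless",
        "versus", "whereas", "instead", "only", "just",
    ],
    "nonflu": [
        "er", "erm", "um", "umm", "uh", "uhh", "hmm", "hm", "mmm", "oh",
        "ohh", "ah", "ahh", "eh", "dunno", "blah", "y'know", "like",
        "anyway", "anyhow",
    ],
}
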