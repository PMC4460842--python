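"""Packaged name pools for the synthetic two-site generator.

Swiss/German/French flavoured, deliberately rich in umlauts and accents so
that transliteration, masking of special characters and cross-site spelling
divergence (ü vs ue) are all exercised.  The male/female first-name pools
include the canonical forms of the packaged nickname table so nickname
substitution round-trips through cleaning.
"""

SURNAMES = [
    "Müller", "Meier", "Meyer", "Schmid", "Schmidt", "Keller", "Weber",
    "Huber", "Schneider", "Steiner", "Fischer", "Brunner", "Baumann",
    "Frei", "Zimmermann", "Moser", "Widmer", "Wyss", "Graf", "Roth",
    "Suter", "Bachmann", "Studer", "Bucher", "Berger", "Kaufmann",
    "Lüthi", "Küng", "Grün", "Schäfer", "Bühler", "Jäggi", "Rüegg",
    "Häfliger", "Lötscher", "Göldi", "Künzli", "Märki", "Röthlisberger",
    "Schürch", "Tröhler", "Vögeli", "Wüthrich", "Zürcher", "Büchi",
    "Dähler", "Egli", "Flückiger", "Gerber", "Hofer", "Imhof", "Jenni",
    "Kohler", "Leu", "Marti", "Nussbaum", "Oberholzer", "Pfister",
    "Rochat", "Favre", "Dubois", "Rossier", "Bonvin", "Besson",
    "Carron", "Delacroix", "Dufour", "Février", "Gillièron", "Héritier",
    "Jaccard", "Lopréno", "Mercier", "Nicoud", "Perret", "Quartier",
    "Rérat", "Savary", "Théraulaz", "Vuille", "Béguin", "Châtelain",
    "Décosterd", "Evéquoz", "Fragnière", "Genoud", "Duc", "Bonnard",
    "Ackermann", "Aebi", "Arnold", "Bader", "Bärtschi", "Beck",
    "Bieri", "Blaser", "Bösch", "Bossert", "Brändli", "Bürgi",
    "Christen", "Dietrich", "Eichenberger", "Erni", "Felber", "Forster",
    "Furrer", "Gasser", "Gfeller", "Glauser", "Gresch", "Grob",
    "Gugger", "Haas", "Häberli", "Hartmann", "Hess", "Hirt",
    "Hostettler", "Hurni", "Iseli", "Jost", "Kälin", "Kern",
    "Knecht", "Koch", "Krebs", "Kunz", "Lanz", "Lehmann",
    "Liechti", "Lustenberger", "Maurer", "Michel", "Minder", "Morf",
    "Näf", "Niederhauser", "Nobs", "Odermatt", "Portmann", "Probst",
    "Ramseier", "Reber", "Renfer", "Ritter", "Rohrer", "Rüfenacht",
    "Salzmann", "Schaller", "Scherrer", "Schläpfer", "Schnyder",
    "Schwab", "Siegenthaler", "Spörri", "Stalder", "Stauffer",
    "Stettler", "Stucki", "Tanner", "Thut", "Tobler", "Trachsel",
    "Uhlmann", "Vogel", "von Allmen", "von der Weid", "Wagner",
    "Walther", "Weibel", "Wenger", "Wermuth", "Wittwer", "Wolf",
    "Wullschleger", "Wüest", "Zaugg", "Zbinden", "Zehnder", "Zwahlen",
]

FIRSTNAMES_M = [
    "Wilhelm", "Johannes", "Josef", "Anton", "Friedrich", "Heinrich",
    "Kurt", "Rudolf", "Ulrich", "Jakob", "Christian", "Beatus",
    "Benedikt", "Max", "Theodor", "Ferdinand", "Albert", "Gustav",
    "Wolfgang", "Karl", "Stefan", "Dominik", "Georg", "Jean",
    "André", "Gabriel", "Hans", "Peter", "Walter", "Werner",
    "Ernst", "Paul", "Otto", "Hermann", "Alfred", "Emil",
    "Robert", "Bruno", "Markus", "Thomas", "Martin", "Daniel",
    "Andreas", "Michael", "Urs", "Beat", "René", "Pierre",
    "Jacques", "François", "Claude", "Michel", "Philippe", "Laurent",
    "Olivier", "Pascal", "Alain", "Bernard", "Henri", "Louis",
    "Marcel", "Raymond", "Roger", "Serge", "Yves", "Étienne",
    "Benoît", "Cédric", "Damien", "Fabien", "Gérard", "Hervé",
    "Adrian", "Lukas", "Matthias", "Niklaus", "Oskar", "Reto",
    "Samuel", "Tobias", "Valentin", "Xaver", "Simon", "David",
    "Erwin", "Fritz", "Gottfried", "Hugo", "Jürg", "Kaspar",
    "Leo", "Armin", "Eduard", "Felix", "Günther", "Jörg",
]

FIRSTNAMES_F = [
    "Anna", "Verena", "Gertrud", "Margaretha", "Theresia", "Elisabeth",
    "Adelheid", "Charlotte", "Maria", "Katharina", "Ursula", "Rosa",
    "Sylvia", "Magdalena", "Barbara", "Franziska", "Susanna", "Marie",
    "Françoise", "Joséphine", "Emma", "Berta", "Clara", "Dora",
    "Erika", "Frieda", "Gerda", "Hedwig", "Ida", "Johanna",
    "Klara", "Lina", "Martha", "Nelly", "Olga", "Paula",
    "Regina", "Selma", "Tilda", "Vreni", "Werna", "Alice",
    "Brigitte", "Christine", "Denise", "Edith", "Gabrielle", "Hélène",
    "Irène", "Jacqueline", "Lucie", "Madeleine", "Nicole", "Odette",
    "Pierrette", "Renée", "Simone", "Thérèse", "Valérie", "Yvonne",
    "Agnes", "Beatrice", "Cécile", "Dorothea", "Eveline", "Felicitas",
    "Gisela", "Heidi", "Ingrid", "Judith", "Karin", "Liselotte",
    "Monika", "Nadine", "Priska", "Ruth", "Sabine", "Trudy",
    "Ulrike", "Vera", "Annemarie", "Bettina", "Corinne", "Doris",
    "Esther", "Flora", "Gret", "Hanna", "Isabelle", "Jolanda",
    "Käthe", "Léonie", "Mireille", "Noëlle", "Oriane", "Pauline",
]
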