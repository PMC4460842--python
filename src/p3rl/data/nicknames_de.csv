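nickname,sex,canonical
WILLI,m,WILHELM
WILLY,m,WILHELM
HANS,m,JOHANNES
HANSI,m,JOHANNES
HANSUELI,m,ULRICH
SEPP,m,JOSEF
SEPPI,m,JOSEF
PEPE,m,JOSEF
TONI,m,ANTON
FRITZ,m,FRIEDRICH
FRIEDEL,m,FRIEDRICH
HEINZ,m,HEINRICH
HEINI,m,HEINRICH
KURTLI,m,KURT
RUDI,m,RUDOLF
RUEDI,m,RUDOLF
UELI,m,ULRICH
UELU,m,ULRICH
KOEBI,m,JAKOB
JOGGI,m,JAKOB
CHRIGEL,m,CHRISTIAN
CHRIGU,m,CHRISTIAN
BEAT,m,BEATUS
BENZ,m,BENEDIKT
MAEX,m,MAX
THEO,m,THEODOR
FERDI,m,FERDINAND
BERTI,m,ALBERT
GUSTI,m,GUSTAV
WOLFI,m,WOLFGANG
KARLI,m,KARL
STEFF,m,STEFAN
DOEME,m,DOMINIK
GEORG,m,GEORGIUS
SCHORSCH,m,GEORG
JEANNOT,m,JEAN
DEDE,m,ANDRE
GABY,m,GABRIEL
ANNELI,f,ANNA
ANNI,f,ANNA
AENNI,f,ANNA
NANNI,f,ANNA
VRENI,f,VERENA
VRENELI,f,VERENA
TRUDI,f,GERTRUD
TRUDE,f,GERTRUD
GRETE,f,MARGARETHA
GRETEL,f,MARGARETHA
GRITLI,f,MARGARETHA
MARGRIT,f,MARGARETHA
RESLI,f,THERESIA
RESI,f,THERESIA
ELSBETH,f,ELISABETH
LISBETH,f,ELISABETH
LISA,f,ELISABETH
BETHLI,f,ELISABETH
BABETTE,f,ELISABETH
HEIDI,f,ADELHEID
LOTTI,f,CHARLOTTE
LOTTE,f,CHARLOTTE
MITZI,f,MARIA
MARELI,f,MARIA
MIGGI,f,MARIA
KAETHI,f,KATHARINA
KAETHE,f,KATHARINA
TRINE,f,KATHARINA
URSI,f,URSULA
USCHI,f,URSULA
ROESLI,f,ROSA
SYLVI,f,SYLVIA
MADLEN,f,MAGDALENA
LENI,f,MAGDALENA
BABS,f,BARBARA
BAERBEL,f,BARBARA
FRANZI,f,FRANZISKA
SUSI,f,SUSANNA
MANON,f,MARIE
FANNY,f,FRANCOISE
JOSETTE,f,JOSEPHINE
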