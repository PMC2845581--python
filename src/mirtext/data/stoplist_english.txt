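WAS
AS
IF
AN
THE
ALL
CAN
HAS
NOT
FOR
SET
MAP
UP
ON
IMPACT
CELL
TYPE
DAMAGE
MICE
RED
LARGE
EARLY
FAST
LIGHT
MASS
PERIOD
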